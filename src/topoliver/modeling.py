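"""Decision-tree classification under stratified 5-fold cross-validation.

The classifier is a fully grown CART decision tree with fixed
hyperparameters (``random_state=33``); performance is summarized by
four metrics — balanced accuracy, weighted F1, AUROC and average
precision — reported per fold and aggregated as median ± median
absolute deviation (MAD, unscaled) across folds.  AUROC uses the
Mann-Whitney rank formulation with ties credited 1/2, which matters
because fully grown trees emit many tied scores.

Also provides descriptive cohort summaries: counts with percentages for
categorical variables, medians with interquartile ranges (type-7
quantiles) for continuous ones.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "TreeHyperparams",
    "EvaluationReport",
    "UndefinedMetricError",
    "stratified_kfold",
    "fit_tree",
    "predict_scores",
    "balanced_accuracy",
    "weighted_f1",
    "auroc",
    "average_precision",
    "aggregate_folds",
    "build_report",
    "cross_validate",
    "cohort_summary",
]


class UndefinedMetricError(ValueError):
    """A metric was requested on labels with only one class present."""


@dataclass(frozen=True)
class TreeHyperparams:
    """Fixed CART hyperparameters: an unpruned tree grown to purity."""

    criterion: str = "gini"
    splitter: str = "best"
    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    min_weight_fraction_leaf: float = 0.0
    max_features: int | None = None
    random_state: int = 33
    max_leaf_nodes: int | None = None
    min_impurity_decrease: float = 0.0
    ccp_alpha: float = 0.0
    class_weight: dict | None = None

    def to_sklearn(self) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(**asdict(self))


@dataclass
class EvaluationReport:
    """Per-fold metric values with median/MAD aggregates and a config echo."""

    fold_metrics: dict[str, list[float]]
    medians: dict[str, float] = field(default_factory=dict)
    mads: dict[str, float] = field(default_factory=dict)
    n_subjects: int = 0
    n_excluded: int = 0
    excluded: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, values in self.fold_metrics.items():
            med, mad = aggregate_folds(values)
            self.medians[name] = med
            self.mads[name] = mad

    def to_dict(self) -> dict:
        return {
            "fold_metrics": self.fold_metrics,
            "medians": self.medians,
            "mads": self.mads,
            "n_subjects": self.n_subjects,
            "n_excluded": self.n_excluded,
            "excluded": self.excluded,
            "config": self.config,
        }


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("metric undefined: only one class present in y")
    return y


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index per subject; class proportions preserved up to rounding."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"stratification impossible: smallest class has {counts.min()} < k={k} members"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        folds[test_idx] = fold
    return folds


def fit_tree(
    features: np.ndarray, labels, hyperparams: TreeHyperparams = TreeHyperparams()
) -> DecisionTreeClassifier:
    features = np.asarray(features, dtype=float)
    if np.isnan(features).any():
        raise ValueError("feature matrix contains missing values")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        warnings.warn("training labels contain a single class; scores will be constant")
    model = hyperparams.to_sklearn()
    model.fit(features, labels)
    return model


def predict_scores(model: DecisionTreeClassifier, features: np.ndarray) -> np.ndarray:
    """Positive-class probability (leaf fraction) per subject."""
    proba = model.predict_proba(np.asarray(features, dtype=float))
    if proba.shape[1] == 1:  # degenerate single-class model
        return np.full(proba.shape[0], float(model.classes_[0] == 1))
    return proba[:, list(model.classes_).index(1)]


def balanced_accuracy(y, y_pred) -> float:
    """(sensitivity + specificity) / 2."""
    y = _check_binary(y)
    return float(skm.balanced_accuracy_score(y, np.asarray(y_pred)))


def weighted_f1(y, y_pred) -> float:
    """Support-weighted mean of per-class F1 scores."""
    y = _check_binary(y)
    return float(skm.f1_score(y, np.asarray(y_pred), average="weighted", zero_division=0))


def auroc(y, scores) -> float:
    """AUROC via the Mann-Whitney rank statistic; ties counted 1/2.

    AUC = (R_pos - n_pos (n_pos + 1) / 2) / (n_pos * n_neg) with R_pos
    the rank sum of positive-class scores (average ranks on ties).
    """
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=float)
    ranks = rankdata(scores)
    n_pos = int(np.sum(y == 1))
    n_neg = len(y) - n_pos
    r_pos = float(ranks[np.asarray(y) == 1].sum())
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def average_precision(y, scores) -> float:
    """Step-sum approximation of the area under the precision-recall curve."""
    y = _check_binary(y)
    return float(skm.average_precision_score(y, np.asarray(scores, dtype=float)))


def aggregate_folds(values) -> tuple[float, float]:
    """(median, unscaled median absolute deviation) of per-fold values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty list of fold values")
    med = float(np.median(values))
    return med, float(np.median(np.abs(values - med)))


def compute_fold_metrics(y_true, y_pred, scores) -> dict[str, float]:
    return {
        "balanced_accuracy": balanced_accuracy(y_true, y_pred),
        "f1_weighted": weighted_f1(y_true, y_pred),
        "auroc": auroc(y_true, scores),
        "average_precision": average_precision(y_true, scores),
    }


def build_report(per_fold: list[dict[str, float]], **kwargs) -> EvaluationReport:
    names = per_fold[0].keys()
    return EvaluationReport(
        fold_metrics={m: [f[m] for f in per_fold] for m in names}, **kwargs
    )


def cross_validate(
    features: np.ndarray,
    labels,
    k: int = 5,
    seed: int = 0,
    hyperparams: TreeHyperparams = TreeHyperparams(),
) -> EvaluationReport:
    """Stratified k-fold CV of the tree on a fixed feature table."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    folds = stratified_kfold(labels, k=k, seed=seed)
    per_fold = []
    for fold in range(k):
        train, test = folds != fold, folds == fold
        model = fit_tree(features[train], labels[train], hyperparams)
        scores = predict_scores(model, features[test])
        per_fold.append(compute_fold_metrics(labels[test], model.predict(features[test]), scores))
    return build_report(per_fold, n_subjects=len(labels), config={"k": k, "seed": seed})


def cohort_summary(
    table: pd.DataFrame,
    categorical: list[str] = (),
    continuous: list[str] = (),
) -> pd.DataFrame:
    """Descriptive summary of subject covariates.

    Categorical columns (0/1 or boolean) are summarized as
    ``count (pct%)`` with the percentage at one decimal; continuous
    columns as ``median [Q1, Q3]`` with linear-interpolation (type-7)
    quantiles.
    """
    if len(table) == 0:
        raise ValueError("empty cohort")
    rows = []
    n = len(table)
    for col in categorical:
        count = int(table[col].astype(bool).sum())
        pct = round(100.0 * count / n, 1)
        rows.append(
            {"variable": col, "count": count, "pct": pct, "summary": f"{count} ({pct}%)"}
        )
    for col in continuous:
        vals = table[col].astype(float).to_numpy()
        med = float(np.median(vals))
        q1, q3 = (float(q) for q in np.quantile(vals, [0.25, 0.75]))
        rows.append(
            {
                "variable": col,
                "median": med,
                "q1": q1,
                "q3": q3,
                "summary": f"{med:g} [{q1:g}, {q3:g}]",
            }
        )
    return pd.DataFrame(rows)
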