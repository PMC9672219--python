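"""Classifier, metrics and aggregation arithmetic."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_curve

from topoliver.modeling import (
    TreeHyperparams,
    UndefinedMetricError,
    aggregate_folds,
    auroc,
    average_precision,
    balanced_accuracy,
    cohort_summary,
    cross_validate,
    fit_tree,
    predict_scores,
    stratified_kfold,
    weighted_f1,
)
from topoliver.reference_cohort import DERIVATION_FOLD_METRICS


class TestStratifiedKfold:
    def test_derivation_cohort_composition(self):
        # 21 positives / 33 negatives in 5 folds: positive counts must be
        # {4,4,4,4,5} up to order, negatives {6,6,7,7,7}, fold sizes 10-11
        labels = np.array([1] * 21 + [0] * 33)
        folds = stratified_kfold(labels, k=5, seed=0)
        pos = sorted(np.sum(labels[folds == f]) for f in range(5))
        neg = sorted(np.sum(labels[folds == f] == 0) for f in range(5))
        sizes = sorted(np.sum(folds == f) for f in range(5))
        assert pos == [4, 4, 4, 4, 5]
        assert neg == [6, 6, 7, 7, 7]
        assert sizes == [10, 11, 11, 11, 11]

    def test_exactly_balanced_case(self):
        folds = stratified_kfold(np.array([0] * 10 + [1] * 10), k=5, seed=1)
        for f in range(5):
            assert np.sum(folds == f) == 4

    def test_deterministic_given_seed(self):
        labels = np.array([0, 1] * 10)
        assert np.array_equal(
            stratified_kfold(labels, seed=5), stratified_kfold(labels, seed=5)
        )

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="stratification"):
            stratified_kfold(np.array([1, 1, 1, 0, 0, 0, 0, 0]), k=5)


class TestTree:
    def test_separable_feature_reaches_purity(self):
        X = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_tree(X, y)
        assert np.array_equal(model.predict(X), y)
        assert np.array_equal(predict_scores(model, X), [0, 0, 1, 1])

    def test_contradictory_rows_score_positive_fraction(self):
        X = np.zeros((4, 1))
        y = np.array([1, 0, 0, 0])
        model = fit_tree(X, y)
        assert predict_scores(model, X) == pytest.approx([0.25] * 4)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            fit_tree(np.array([[np.nan]]), np.array([1]))

    def test_single_class_training_warns_and_scores_constant(self):
        with pytest.warns(UserWarning, match="single class"):
            model = fit_tree(np.array([[0.0], [1.0]]), np.array([0, 0]))
        assert np.array_equal(predict_scores(model, np.array([[0.5]])), [0.0])

    def test_default_hyperparameters_are_the_fixed_set(self):
        hp = TreeHyperparams()
        assert (hp.criterion, hp.splitter, hp.random_state) == ("gini", "best", 33)
        assert hp.max_depth is None and hp.ccp_alpha == 0.0


class TestMetrics:
    def test_perfect_prediction_all_metrics_one(self):
        y = np.array([1, 0, 1, 0, 1])
        for metric in (balanced_accuracy, weighted_f1):
            assert metric(y, y) == 1.0
        for metric in (auroc, average_precision):
            assert metric(y, y.astype(float)) == 1.0

    def test_all_positive_prediction_is_chance_balanced_accuracy(self):
        y = np.array([1, 1, 0, 0, 1])
        assert balanced_accuracy(y, np.ones_like(y)) == 0.5

    def test_hand_computed_confusion_matrix(self):
        y = np.array([1, 1, 1, 0, 0])
        y_pred = np.array([1, 0, 1, 0, 1])
        # sensitivity 2/3, specificity 1/2
        assert balanced_accuracy(y, y_pred) == pytest.approx((2 / 3 + 1 / 2) / 2)

    def test_auroc_by_pair_enumeration(self):
        y = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        assert auroc(y, scores) == pytest.approx(3 / 4)  # 3 of 4 pairs ordered

    def test_auroc_all_ties_is_half(self):
        y = np.array([1, 0, 1, 0])
        assert auroc(y, np.full(4, 0.3)) == pytest.approx(0.5)

    def test_one_class_labels_rejected(self):
        y = np.ones(4, dtype=int)
        for metric in (balanced_accuracy, weighted_f1, auroc, average_precision):
            with pytest.raises(UndefinedMetricError):
                metric(y, y.astype(float))

    def test_metrics_invariant_to_subject_order(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        scores = rng.random(30)
        perm = rng.permutation(30)
        assert auroc(y, scores) == pytest.approx(auroc(y[perm], scores[perm]))
        assert average_precision(y, scores) == pytest.approx(
            average_precision(y[perm], scores[perm])
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_rank_auroc_equals_trapezoidal_roc_area(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        scores = np.round(rng.random(40), 2)  # rounding forces ties
        fpr, tpr, _ = roc_curve(y, scores)
        assert auroc(y, scores) == pytest.approx(np.trapezoid(tpr, fpr))


class TestAggregation:
    def test_reported_fold_medians(self):
        med_ba, mad_ba = aggregate_folds(DERIVATION_FOLD_METRICS["balanced_accuracy"])
        assert med_ba == pytest.approx(0.80)
        assert mad_ba == pytest.approx(0.11)
        med_ap, _ = aggregate_folds(DERIVATION_FOLD_METRICS["average_precision"])
        assert med_ap == pytest.approx(0.74)
        med_auc, _ = aggregate_folds(DERIVATION_FOLD_METRICS["auroc"])
        assert med_auc == pytest.approx(0.80)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([])

    def test_median_within_fold_range(self, rng):
        values = rng.random(5)
        med, mad = aggregate_folds(values)
        assert values.min() <= med <= values.max()
        assert mad >= 0


class TestCrossValidate:
    def test_separable_features_score_perfectly(self, rng):
        X = np.concatenate([rng.random((10, 3)), rng.random((10, 3)) + 5])
        y = np.array([0] * 10 + [1] * 10)
        report = cross_validate(X, y, k=5, seed=0)
        assert report.medians["auroc"] == 1.0
        assert all(0 <= v <= 1 for v in report.medians.values())

    def test_report_medians_lie_within_fold_extremes(self, rng):
        X = rng.random((30, 4))
        y = np.array([0, 1] * 15)
        report = cross_validate(X, y, k=5, seed=3)
        for name, folds in report.fold_metrics.items():
            assert min(folds) <= report.medians[name] <= max(folds)


class TestCohortSummary:
    def test_reported_percentages(self):
        table = pd.DataFrame(
            {"female": [1] * 21 + [0] * 33, "ibd": [1] * 49 + [0] * 5}
        )
        out = cohort_summary(table, categorical=["female", "ibd"]).set_index("variable")
        assert out.loc["female", "pct"] == 38.9
        assert out.loc["female", "summary"] == "21 (38.9%)"
        assert out.loc["ibd", "pct"] == 90.7

    def test_median_and_iqr(self):
        table = pd.DataFrame({"age": [1, 2, 3, 4, 5]})
        out = cohort_summary(table, continuous=["age"]).iloc[0]
        assert (out["median"], out["q1"], out["q3"]) == (3.0, 2.0, 4.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_summary(pd.DataFrame(), categorical=["x"])
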