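"""End-to-end orchestration: masked slices -> topology -> features -> CV.

For every subject the pipeline selects 25 liver-dominated patches,
tiles them into a mosaic, computes sublevel-set cubical persistence,
caps essential intervals, and — inside each cross-validation fold —
fits the persistence-image grid (bounds, bandwidth, weight normalizer)
on the training subjects only before rasterizing, extracting LBP
histograms and training the decision tree.  Subjects whose mask cannot
supply 25 qualifying patches are excluded (not fatal) and listed in the
report, mirroring clinical exclusion for inadequate liver coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .config import PipelineConfig
from .homology import PersistenceDiagram, betti_curve, build_complex, cap_infinite, compute_persistence
from .lbp import lbp_histogram
from .modeling import (
    EvaluationReport,
    build_report,
    compute_fold_metrics,
    fit_tree,
    predict_scores,
    stratified_kfold,
)
from .patching import InsufficientLiverCoverage, PatchSpec, assemble_mosaic, pick_slice, select_patches
from .pimage import ImageGrid, grid_from_diagrams, vectorize_pair

log = logging.getLogger("topoliver")

POSITIVE_LABEL = "decomp"

__all__ = ["Subject", "subject_diagram", "feature_vector", "run_pipeline", "subjects_from_manifest"]


@dataclass
class Subject:
    subject_id: str
    image: np.ndarray
    mask: np.ndarray
    label: str


def subjects_from_manifest(manifest: pd.DataFrame, profiles=None) -> list[Subject]:
    """Materialize subjects from a cohort manifest (files or phantom seeds)."""
    from .phantom import cohort_arrays

    return [
        Subject(sid, img, msk, label)
        for sid, img, msk, label in cohort_arrays(manifest, profiles)
    ]


def subject_mosaic(subject: Subject, config: PipelineConfig) -> np.ndarray:
    image, mask = subject.image, subject.mask
    if image.ndim == 3:
        idx = pick_slice(image, mask)
        image, mask = image[:, :, idx], mask[:, :, idx]
    if config.superlevel:
        image = -image
    spec = PatchSpec(patch_size=config.patch_size, stride=config.stride)
    origins = select_patches(image, mask, spec)
    return assemble_mosaic(image, origins, spec).pixels


def subject_diagram(subject: Subject, config: PipelineConfig) -> PersistenceDiagram:
    """Capped persistence diagram of one subject's mosaic."""
    mosaic = subject_mosaic(subject, config)
    diagram = compute_persistence(build_complex(mosaic))
    return cap_infinite(diagram, config.cap_policy)


def feature_vector(
    diagram: PersistenceDiagram, grid: ImageGrid, config: PipelineConfig
) -> np.ndarray:
    """LBP histograms of the H0/H1 persistence images, concatenated."""
    images = vectorize_pair(diagram, grid)
    parts = [lbp_histogram(images[d], config.lbp).values for d in config.use_dims]
    return np.concatenate(parts)


def feature_names(config: PipelineConfig) -> list[str]:
    from .lbp import lbp_histogram as _h

    probe = np.zeros((3, 3))
    names = _h(probe, config.lbp).names
    return [f"h{d}_{n}" for d in config.use_dims for n in names]


def run_pipeline(
    subjects: list[Subject],
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
    force: bool = False,
) -> EvaluationReport:
    """Cross-validated evaluation of the full pipeline on a cohort.

    Persistence diagrams are computed once per subject; everything
    fitted on data (persistence-image grid, tree) is re-fitted inside
    each fold on the training subjects only.
    """
    if out_dir is not None:
        out_dir = Path(out_dir)
        if (out_dir / "report.json").exists() and not force:
            raise FileExistsError(f"{out_dir} already holds a completed run (use force)")
        out_dir.mkdir(parents=True, exist_ok=True)

    diagrams: list[PersistenceDiagram] = []
    kept: list[Subject] = []
    excluded: list[dict] = []
    for subject in subjects:
        try:
            diagrams.append(subject_diagram(subject, config))
            kept.append(subject)
        except InsufficientLiverCoverage as err:
            log.info("excluding %s: %s", subject.subject_id, err)
            excluded.append({"subject_id": subject.subject_id, "reason": str(err)})

    labels = np.array([int(s.label == POSITIVE_LABEL) for s in kept])
    if len(np.unique(labels)) < 2 or min(np.bincount(labels)) < config.k:
        raise RuntimeError(
            f"fewer than k={config.k} subjects per class remain after "
            f"{len(excluded)} exclusion(s); cannot stratify"
        )

    folds = stratified_kfold(labels, k=config.k, seed=config.cv_seed)
    per_fold = []
    for fold in range(config.k):
        train = folds != fold
        grid = grid_from_diagrams(
            [d for d, t in zip(diagrams, train) if t],
            resolution=config.resolution,
            sigma_scale=config.sigma_scale,
        )
        feats = np.stack([feature_vector(d, grid, config) for d in diagrams])
        model = fit_tree(feats[train], labels[train], config.tree)
        test = ~train
        per_fold.append(
            compute_fold_metrics(
                labels[test], model.predict(feats[test]), predict_scores(model, feats[test])
            )
        )
        log.info("fold %d: %s", fold, per_fold[-1])

    report = build_report(
        per_fold,
        n_subjects=len(kept),
        n_excluded=len(excluded),
        excluded=excluded,
        config=config.to_dict(),
    )

    if out_dir is not None:
        _write_artifacts(out_dir, kept, diagrams, labels, report, config)
    return report


def _write_artifacts(out_dir: Path, subjects, diagrams, labels, report, config) -> None:
    """Persist config, per-subject diagrams/curves, features and the report."""
    config.to_yaml(out_dir / "config.yaml")
    (out_dir / "diagrams").mkdir(exist_ok=True)
    (out_dir / "betti").mkdir(exist_ok=True)
    for s, d in zip(subjects, diagrams):
        tio.write_diagram(out_dir / "diagrams" / f"{s.subject_id}.csv", d)
        tio.write_betti_curve(out_dir / "betti" / f"{s.subject_id}.csv", betti_curve(d))
    # final feature table on a grid fitted to the full cohort
    grid = grid_from_diagrams(diagrams, resolution=config.resolution, sigma_scale=config.sigma_scale)
    feats = np.stack([feature_vector(d, grid, config) for d in diagrams])
    table = pd.DataFrame(feats, columns=feature_names(config))
    table.insert(0, "subject_id", [s.subject_id for s in subjects])
    table["label"] = labels
    table.to_csv(out_dir / "features.csv", index=False)
    tio.write_json(out_dir / "report.json", report.to_dict())
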