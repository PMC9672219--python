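"""Synthetic liver-slice phantoms with controlled topology.

Real patient images for the decompensation-prediction task are not
shareable, so this module generates seeded stand-ins: an elliptical
"liver" mask over a constant background, populated with two kinds of
dark primitives whose topology is known by construction — disks
("blobs"), which control connected components (H0), and annuli
("rings"), whose interior stays at background intensity so each
contributes exactly one loop (H1) with persistence equal to the contrast
depth.  Correlated Gaussian noise is added inside the mask.

Two class profiles emulate the contrast between patients who do and do
not decompensate within a year:

* ``decomp`` — many small, low-contrast, clustered primitives and a
  smooth low-amplitude noise field: topological features are numerous
  but short-lived, and few are alive at any one threshold, so Betti
  numbers stay in a small range.
* ``no_decomp`` — fewer, larger, higher-contrast primitives and a
  rougher higher-amplitude noise field: features persist longer, many
  coexist, and Betti numbers span a much wider range.

All randomness flows through a single integer seed; identical
parameters and seed give bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomParams",
    "ClassProfile",
    "PlacementError",
    "default_profiles",
    "generate_phantom",
    "generate_cohort",
    "cohort_arrays",
]


class PlacementError(RuntimeError):
    """Rejection sampling could not place all features without overlap."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, texture and noise parameters of one phantom class.

    Intensities are floats in [0, 1]: background 0.5 inside the liver
    ellipse, 1.0 outside (enters the sublevel filtration last), and
    dark primitives at ``0.5 - contrast_depth``.  ``noise_sigma``
    defaults to ``0.1 * contrast_depth``; ``noise_smoothing`` is the
    Gaussian correlation length of the noise field in pixels.
    """

    image_size: int = 128
    liver_center: tuple[float, float] = (64.0, 64.0)
    liver_axes: tuple[float, float] = (48.0, 58.0)
    n_blobs: int = 20
    n_rings: int = 8
    blob_radius_range: tuple[float, float] = (2.0, 4.0)
    ring_radius_range: tuple[float, float] = (5.0, 9.0)
    ring_width: float = 2.0
    contrast_depth: float = 0.25
    noise_sigma: float | None = None  # None -> 0.1 * contrast_depth
    noise_smoothing: float = 1.5
    background: float = 0.5
    outside: float = 1.0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.n_blobs < 0 or self.n_rings < 0:
            raise ValueError("feature counts must be >= 0")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.ring_radius_range[0] < self.ring_width + 1.5:
            raise ValueError("ring radius must leave an interior (radius >= width + 1.5)")

    @property
    def effective_noise_sigma(self) -> float:
        return 0.1 * self.contrast_depth if self.noise_sigma is None else self.noise_sigma


@dataclass(frozen=True)
class ClassProfile:
    label: str  # "decomp" or "no_decomp"
    params: PhantomParams


def default_profiles() -> tuple[ClassProfile, ClassProfile]:
    """Default two-class study conditions.

    The decompensating class has more, smaller, lower-contrast rings and
    blobs (short-lived features) over a smoother noise field; the
    non-decompensating class fewer, larger, higher-contrast primitives
    over a rougher field (longer-lived features, wider Betti range).
    """
    decomp = ClassProfile(
        label="decomp",
        params=PhantomParams(
            n_blobs=30,
            n_rings=12,
            blob_radius_range=(2.0, 3.0),
            ring_radius_range=(3.5, 5.0),
            ring_width=2.0,
            contrast_depth=0.15,
            noise_smoothing=2.0,
        ),
    )
    no_decomp = ClassProfile(
        label="no_decomp",
        params=PhantomParams(
            n_blobs=10,
            n_rings=5,
            blob_radius_range=(4.0, 7.0),
            ring_radius_range=(8.0, 14.0),
            ring_width=3.0,
            contrast_depth=0.35,
            noise_smoothing=1.0,
        ),
    )
    return decomp, no_decomp


def _ellipse_mask(n: int, center: tuple[float, float], axes: tuple[float, float]) -> np.ndarray:
    ii, jj = np.mgrid[0:n, 0:n]
    a, b = axes
    return (((ii - center[0]) / a) ** 2 + ((jj - center[1]) / b) ** 2 <= 1.0).astype(np.uint8)


def _place_features(params: PhantomParams, rng: np.random.Generator, seed: int):
    """Seeded rejection sampling of non-overlapping feature centers.

    Each feature (disk or annulus) must lie entirely inside the liver
    ellipse and must not touch any previously placed feature, so the
    designed topology is exactly realized.
    """
    placed: list[tuple[float, float, float, str]] = []  # (i, j, radius, kind)
    specs = [("blob", params.blob_radius_range)] * params.n_blobs + [
        ("ring", params.ring_radius_range)
    ] * params.n_rings
    # draw all radii up front and place largest-first: sequential random
    # placement jams if small features are laid down before large ones
    features = [(kind, float(rng.uniform(*rrange))) for kind, rrange in specs]
    features.sort(key=lambda kr: -kr[1])
    ci, cj = params.liver_center
    a, b = params.liver_axes
    for kind, radius in features:
        # shrink the ellipse so the whole feature fits inside the mask
        ea, eb = a - radius - 1.0, b - radius - 1.0
        if ea <= 0 or eb <= 0:
            raise PlacementError(
                f"{kind} of radius {radius:.1f} cannot fit the liver ellipse (seed={seed})"
            )
        for _ in range(params.max_attempts):
            t = rng.uniform(0, 2 * np.pi)
            u = np.sqrt(rng.uniform())
            i = ci + ea * u * np.cos(t)
            j = cj + eb * u * np.sin(t)
            if all(
                np.hypot(i - pi, j - pj) >= radius + pr + 2.0 for pi, pj, pr, _ in placed
            ):
                placed.append((i, j, radius, kind))
                break
        else:
            raise PlacementError(
                f"could not place {kind} after {params.max_attempts} attempts (seed={seed})"
            )
    return placed


def generate_phantom(
    profile: ClassProfile, seed: int
) -> tuple[np.ndarray, np.ndarray, str]:
    """One phantom slice: (image, mask, label), floats in [0, 1]."""
    params = profile.params
    n = params.image_size
    rng = np.random.default_rng(seed)
    mask = _ellipse_mask(n, params.liver_center, params.liver_axes)
    img = np.full((n, n), params.outside, dtype=float)
    img[mask == 1] = params.background

    dark = params.background - params.contrast_depth
    ii, jj = np.mgrid[0:n, 0:n]
    for fi, fj, radius, kind in _place_features(params, rng, seed):
        dist = np.hypot(ii - fi, jj - fj)
        if kind == "blob":
            img[dist <= radius] = dark
        else:  # ring: annulus of width ring_width; interior stays background
            img[(dist <= radius) & (dist >= radius - params.ring_width)] = dark

    sigma = params.effective_noise_sigma
    if sigma > 0:
        noise = rng.standard_normal((n, n))
        if params.noise_smoothing > 0:
            noise = ndimage.gaussian_filter(noise, params.noise_smoothing)
        noise *= sigma / noise.std()
        img[mask == 1] += noise[mask == 1]
        np.clip(img, 0.0, 1.0, out=img)
    return img, mask, profile.label


def generate_cohort(
    n_per_class: int,
    profiles: tuple[ClassProfile, ClassProfile] | None = None,
    seed: int = 0,
    out_dir=None,
) -> pd.DataFrame:
    """Manifest of a balanced two-class cohort.

    Returns a DataFrame with columns ``subject_id, image, mask, label,
    seed``; each subject gets an independent sub-seed drawn from the
    cohort seed, so any subject can be regenerated in isolation.  When
    ``out_dir`` is given, images and masks are written there as
    single-slice NIfTI volumes and the manifest as ``manifest.csv``;
    otherwise the path columns are empty and :func:`cohort_arrays`
    regenerates the arrays from the manifest seeds.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=2 * n_per_class)
    records = []
    k = 0
    for profile in profiles:
        for i in range(n_per_class):
            records.append(
                {
                    "subject_id": f"{profile.label}_{i:03d}",
                    "image": "",
                    "mask": "",
                    "label": profile.label,
                    "seed": int(sub_seeds[k]),
                }
            )
            k += 1
    manifest = pd.DataFrame.from_records(records)
    if out_dir is not None:
        from . import io as tio
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        by_label = {p.label: p for p in profiles}
        for idx, row in manifest.iterrows():
            img, msk, _ = generate_phantom(by_label[row["label"]], int(row["seed"]))
            ipath = out_dir / f"{row['subject_id']}_image.nii"
            mpath = out_dir / f"{row['subject_id']}_mask.nii"
            tio.write_nifti(ipath, img)
            tio.write_nifti(mpath, msk)
            manifest.loc[idx, "image"] = str(ipath)
            manifest.loc[idx, "mask"] = str(mpath)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def cohort_arrays(
    manifest: pd.DataFrame,
    profiles: tuple[ClassProfile, ClassProfile] | None = None,
):
    """Yield (subject_id, image, mask, label) for each manifest row.

    Rows with file paths are loaded from disk; rows without are
    regenerated from their stored sub-seed and the class profile.
    """
    if profiles is None:
        profiles = default_profiles()
    by_label = {p.label: p for p in profiles}
    for _, row in manifest.iterrows():
        path = row["image"]
        if isinstance(path, str) and path:
            from . import io as tio

            img, msk = tio.read_volume(row["image"], row["mask"])
        else:
            img, msk, _ = generate_phantom(by_label[row["label"]], int(row["seed"]))
        yield row["subject_id"], img, msk, row["label"]
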