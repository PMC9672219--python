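"""Liver-patch selection and mosaic assembly.

From a masked grayscale slice, 25 patches lying primarily inside the
liver (at least 80% liver pixels) are selected on a non-overlapping
stride grid and tiled row-major into a single 5x5 mosaic — the image the
topology stage consumes.  Selection is deterministic: candidate windows
are ranked by descending liver fraction with ties broken by row-major
scan order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatchSpec",
    "Mosaic",
    "InsufficientLiverCoverage",
    "liver_fraction",
    "select_patches",
    "assemble_mosaic",
    "pick_slice",
]


class InsufficientLiverCoverage(ValueError):
    """Fewer than the required number of liver-dominated windows exist."""


@dataclass(frozen=True)
class PatchSpec:
    """Patch-selection parameters.

    The patch count (25) and liver-fraction threshold (0.80) are fixed
    by the method; patch size and stride are configurable (stride
    defaults to the patch size, i.e. a non-overlapping grid).
    """

    patch_size: int = 32
    stride: int | None = None
    n_patches: int = 25
    liver_fraction_min: float = 0.80

    def __post_init__(self) -> None:
        if self.patch_size < 3:
            raise ValueError("patch_size must be >= 3")
        if self.n_patches != 25 or self.liver_fraction_min != 0.80:
            raise ValueError("the method fixes 25 patches at liver fraction >= 0.80")

    @property
    def step(self) -> int:
        return self.stride if self.stride is not None else self.patch_size


@dataclass(frozen=True)
class Mosaic:
    """5x5 tiling of selected patches plus the source origin of each tile."""

    pixels: np.ndarray
    provenance: tuple[tuple[int, int], ...]
    patch_size: int

    def tile(self, index: int) -> np.ndarray:
        s = self.patch_size
        i, j = divmod(index, 5)
        return self.pixels[i * s : (i + 1) * s, j * s : (j + 1) * s]


def _check_pair(slice_: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    slice_ = np.asarray(slice_, dtype=float)
    mask = np.asarray(mask)
    if slice_.shape != mask.shape:
        raise ValueError(f"slice shape {slice_.shape} != mask shape {mask.shape}")
    return slice_, mask


def liver_fraction(mask: np.ndarray, origin: tuple[int, int], size: int) -> float:
    """Fraction of mask-positive pixels in the ``size x size`` window at ``origin``."""
    mask = np.asarray(mask)
    i, j = origin
    if i < 0 or j < 0 or i + size > mask.shape[0] or j + size > mask.shape[1]:
        raise IndexError(f"window at {origin} of size {size} exceeds image bounds {mask.shape}")
    return float(np.count_nonzero(mask[i : i + size, j : j + size])) / (size * size)


def select_patches(
    slice_: np.ndarray, mask: np.ndarray, spec: PatchSpec = PatchSpec()
) -> tuple[tuple[int, int], ...]:
    """The 25 stride-grid windows with the highest liver fraction.

    Raises :class:`InsufficientLiverCoverage` when fewer than 25 windows
    reach the 0.80 threshold — such exams are excluded upstream.
    """
    slice_, mask = _check_pair(slice_, mask)
    s, step = spec.patch_size, spec.step
    rows = range(0, slice_.shape[0] - s + 1, step)
    cols = range(0, slice_.shape[1] - s + 1, step)
    candidates = [
        ((i, j), liver_fraction(mask, (i, j), s)) for i in rows for j in cols
    ]
    qualifying = [(o, f) for o, f in candidates if f >= spec.liver_fraction_min]
    if len(qualifying) < spec.n_patches:
        raise InsufficientLiverCoverage(
            f"only {len(qualifying)} windows reach liver fraction "
            f">= {spec.liver_fraction_min} (need {spec.n_patches})"
        )
    # descending fraction; ties by row-major scan order (candidates are scanned
    # row-major already, and the sort is stable)
    qualifying.sort(key=lambda of: -of[1])
    return tuple(o for o, _ in qualifying[: spec.n_patches])


def assemble_mosaic(
    slice_: np.ndarray, origins, spec: PatchSpec = PatchSpec()
) -> Mosaic:
    """Tile 25 patches row-major into a (5s, 5s) mosaic; pixels are copied."""
    slice_ = np.asarray(slice_, dtype=float)
    origins = tuple((int(i), int(j)) for i, j in origins)
    if len(origins) != 25:
        raise ValueError(f"expected 25 origins, got {len(origins)}")
    s = spec.patch_size
    out = np.empty((5 * s, 5 * s), dtype=float)
    for k, (i, j) in enumerate(origins):
        ti, tj = divmod(k, 5)
        out[ti * s : (ti + 1) * s, tj * s : (tj + 1) * s] = slice_[i : i + s, j : j + s]
    return Mosaic(pixels=out, provenance=origins, patch_size=s)


def pick_slice(volume: np.ndarray, mask_volume: np.ndarray) -> int:
    """Index (last axis) of the slice with the largest liver area; ties -> smallest index."""
    volume = np.asarray(volume)
    mask_volume = np.asarray(mask_volume)
    if volume.shape != mask_volume.shape:
        raise ValueError("volume and mask shapes differ")
    areas = np.count_nonzero(mask_volume.reshape(-1, mask_volume.shape[-1]), axis=0)
    if areas.sum() == 0:
        raise ValueError("mask volume is empty")
    return int(np.argmax(areas))
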