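"""Sublevel-set cubical persistent homology of grayscale images.

A 2-D image is turned into a filtered cubical complex with the
T-construction: every pixel is a top-dimensional square carrying its own
intensity, and each lower-dimensional face (edge, vertex) carries the
minimum intensity over the pixels it bounds.  The sublevel set at
threshold ``eps`` is then exactly the union of the closed pixels with
intensity <= ``eps``, so connected components of the sublevel set follow
8-connectivity.  Persistent homology in dimensions 0 (components) and 1
(loops) is computed by standard boundary-matrix reduction over Z/2, and
an independent union-find / Euler-characteristic oracle
(:func:`brute_force_betti`) is provided for cross-validation of the
Betti curves.

Conventions
-----------
* Filtration direction is sublevel (dark features enter first).  Negate
  the image for superlevel filtrations.
* Cells are ordered by (filtration value, dimension, row-major position),
  horizontal edges before vertical edges at equal value.
* Coefficients are Z/2.
* Essential classes have death ``+inf``; :func:`cap_infinite` replaces
  the infinite death by the global intensity maximum before
  vectorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "FilteredCubicalComplex",
    "PersistenceInterval",
    "PersistenceDiagram",
    "BettiCurve",
    "build_complex",
    "compute_persistence",
    "brute_force_betti",
    "betti_curve",
    "cap_infinite",
]

_EIGHT = np.ones((3, 3), dtype=int)


class NonMonotoneError(ValueError):
    """A face carries a larger filtration value than one of its cofaces."""


@dataclass(frozen=True)
class PersistenceInterval:
    """One (birth, death) interval of the filtration.

    ``death`` is ``+inf`` for essential classes; ``essential`` records
    that fact so it survives capping.
    """

    dim: int
    birth: float
    death: float
    essential: bool = False

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of persistence intervals plus provenance of the image."""

    intervals: tuple[PersistenceInterval, ...]
    shape: tuple[int, int]
    vmin: float
    vmax: float
    critical_values: tuple[float, ...] = field(default=())

    def by_dim(self, dim: int) -> tuple[PersistenceInterval, ...]:
        return tuple(iv for iv in self.intervals if iv.dim == dim)

    @property
    def essentials(self) -> tuple[PersistenceInterval, ...]:
        return tuple(iv for iv in self.intervals if iv.essential)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class BettiCurve:
    """Piecewise-constant Betti numbers b0, b1 sampled at the critical values."""

    thresholds: np.ndarray
    b0: np.ndarray
    b1: np.ndarray


class FilteredCubicalComplex:
    """Filtered cubical complex of an ``r x c`` image (T-construction).

    Cell counts are ``V=(r+1)(c+1)``, ``E=r(c+1)+c(r+1)``, ``F=r*c``.
    ``vertex_values``, ``hedge_values``, ``vedge_values`` and
    ``face_values`` hold per-cell filtration values; a horizontal edge at
    (i, j) joins vertices (i, j)-(i, j+1), a vertical edge at (i, j)
    joins (i, j)-(i+1, j).
    """

    def __init__(self, face_values: np.ndarray) -> None:
        img = np.asarray(face_values, dtype=float)
        if img.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {img.shape}")
        if not np.all(np.isfinite(img)):
            raise ValueError("image contains non-finite intensities")
        r, c = img.shape
        pad = np.full((r + 2, c + 2), np.inf)
        pad[1:-1, 1:-1] = img
        # face value of a lower cell = min over the pixels it bounds
        self.vertex_values = np.minimum.reduce(
            [
                pad[0 : r + 1, 0 : c + 1],
                pad[0 : r + 1, 1 : c + 2],
                pad[1 : r + 2, 0 : c + 1],
                pad[1 : r + 2, 1 : c + 2],
            ]
        )
        self.hedge_values = np.minimum(pad[0 : r + 1, 1 : c + 1], pad[1 : r + 2, 1 : c + 1])
        self.vedge_values = np.minimum(pad[1 : r + 1, 0 : c + 1], pad[1 : r + 1, 1 : c + 2])
        self.face_values = img
        self.shape = (r, c)

    @property
    def n_vertices(self) -> int:
        r, c = self.shape
        return (r + 1) * (c + 1)

    @property
    def n_edges(self) -> int:
        r, c = self.shape
        return r * (c + 1) + c * (r + 1)

    @property
    def n_faces(self) -> int:
        r, c = self.shape
        return r * c

    def validate_monotone(self) -> None:
        """Raise :class:`NonMonotoneError` if any face exceeds a coface."""
        r, c = self.shape
        he, ve, fv, vv = self.hedge_values, self.vedge_values, self.face_values, self.vertex_values
        ok = (
            np.all(he[:r, :] <= fv + 1e-12),
            np.all(he[1:, :] <= fv + 1e-12),
            np.all(ve[:, :c] <= fv + 1e-12),
            np.all(ve[:, 1:] <= fv + 1e-12),
            np.all(vv[:, :c] <= he + 1e-12),
            np.all(vv[:, 1:] <= he + 1e-12),
            np.all(vv[:r, :] <= ve + 1e-12),
            np.all(vv[1:, :] <= ve + 1e-12),
        )
        if not all(ok):
            raise NonMonotoneError("filtration is not monotone: a face exceeds a coface")


def build_complex(mosaic: np.ndarray) -> FilteredCubicalComplex:
    """Build the sublevel-set filtered cubical complex of a grayscale image."""
    return FilteredCubicalComplex(mosaic)


def _positional_order(values: np.ndarray) -> np.ndarray:
    """Sort by (value, row-major position); stable argsort gives the tie rule."""
    return np.argsort(values.ravel(), kind="stable")


def compute_persistence(
    cplx: FilteredCubicalComplex, include_zero: bool = False
) -> PersistenceDiagram:
    """H0/H1 persistence by boundary-matrix reduction over Z/2.

    Columns are reduced per dimension with the clearing optimization
    (faces first; edges paired as deaths of 1-cycles are skipped).
    Zero-persistence pairs (birth == death) are dropped unless
    ``include_zero`` is set; they carry zero weight downstream.
    """
    cplx.validate_monotone()
    r, c = cplx.shape
    nv, nhe = (r + 1) * (c + 1), (r + 1) * c
    nve = r * (c + 1)

    vvals = cplx.vertex_values.ravel()
    evals = np.concatenate([cplx.hedge_values.ravel(), cplx.vedge_values.ravel()])
    fvals = cplx.face_values.ravel()

    vorder = _positional_order(vvals)
    vpos = np.empty(nv, dtype=np.int64)
    vpos[vorder] = np.arange(nv)
    eorder = _positional_order(evals)
    epos = np.empty(nhe + nve, dtype=np.int64)
    epos[eorder] = np.arange(nhe + nve)
    forder = _positional_order(fvals)

    # boundary of face (i, j): h-edges (i, j), (i+1, j); v-edges (i, j), (i, j+1)
    fi, fj = np.divmod(np.arange(r * c), c)
    face_bnd = epos[
        np.stack(
            [fi * c + fj, (fi + 1) * c + fj, nhe + fi * (c + 1) + fj, nhe + fi * (c + 1) + fj + 1],
            axis=1,
        )
    ]
    # boundary of an edge: its two vertices
    hei, hej = np.divmod(np.arange(nhe), c)
    vei, vej = np.divmod(np.arange(nve), c + 1)
    edge_bnd = np.empty((nhe + nve, 2), dtype=np.int64)
    edge_bnd[:nhe, 0] = hei * (c + 1) + hej
    edge_bnd[:nhe, 1] = hei * (c + 1) + hej + 1
    edge_bnd[nhe:, 0] = vei * (c + 1) + vej
    edge_bnd[nhe:, 1] = (vei + 1) * (c + 1) + vej
    edge_bnd = vpos[edge_bnd]

    intervals: list[PersistenceInterval] = []

    # --- dim 2 columns: pairs (edge birth, face death) are H1 intervals
    low_to_col: dict[int, int] = {}
    cleared = np.zeros(nhe + nve, dtype=bool)
    for f in forder:
        col = 0
        for e in face_bnd[f]:
            col ^= 1 << int(e)
        while col:
            low = col.bit_length() - 1
            other = low_to_col.get(low)
            if other is None:
                low_to_col[low] = col
                birth = float(evals[eorder[low]])
                death = float(fvals[f])
                cleared[eorder[low]] = True
                if include_zero or death > birth:
                    intervals.append(PersistenceInterval(1, birth, death))
                break
            col ^= other
        # a zero column would mean a 2-cycle: impossible in 2-D with boundary

    # --- dim 1 columns (cleared ones skipped): pairs (vertex, edge) are H0
    low_to_col0: dict[int, int] = {}
    paired_vpos: set[int] = set()
    for epos_i, ei in enumerate(eorder):
        if cleared[ei]:
            continue
        col = (1 << int(edge_bnd[ei, 0])) | (1 << int(edge_bnd[ei, 1]))
        essential_h1 = True
        while col:
            low = col.bit_length() - 1
            other = low_to_col0.get(low)
            if other is None:
                low_to_col0[low] = col
                paired_vpos.add(low)
                birth = float(vvals[vorder[low]])
                death = float(evals[ei])
                if include_zero or death > birth:
                    intervals.append(PersistenceInterval(0, birth, death))
                essential_h1 = False
                break
            col ^= other
        if essential_h1:
            # edge column reduced to zero and never killed by a face
            intervals.append(
                PersistenceInterval(1, float(evals[ei]), np.inf, essential=True)
            )

    # unpaired vertices are essential H0 classes (one per component)
    for pos in range(nv):
        if pos not in paired_vpos:
            intervals.append(
                PersistenceInterval(0, float(vvals[vorder[pos]]), np.inf, essential=True)
            )

    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].dim, intervals[i].birth, intervals[i].death))
    crit = np.unique(cplx.face_values)
    return PersistenceDiagram(
        intervals=tuple(intervals[i] for i in order),
        shape=cplx.shape,
        vmin=float(np.min(cplx.face_values)),
        vmax=float(np.max(cplx.face_values)),
        critical_values=tuple(float(v) for v in crit),
    )


def brute_force_betti(mosaic: np.ndarray, eps: float) -> tuple[int, int]:
    """Independent Betti-number oracle at a single threshold.

    ``b0`` is the number of 8-connected components of the pixel sublevel
    set; ``b1 = b0 - chi`` with ``chi = V - E + F`` counted over all
    cells whose filtration value is <= ``eps``.  Shares no code with the
    boundary-matrix reduction.
    """
    img = np.asarray(mosaic, dtype=float)
    sub = img <= eps
    if not sub.any():
        return (0, 0)
    b0 = int(ndimage.label(sub, structure=_EIGHT)[1])
    cplx = FilteredCubicalComplex(img)
    V = int(np.count_nonzero(cplx.vertex_values <= eps))
    E = int(np.count_nonzero(cplx.hedge_values <= eps)) + int(
        np.count_nonzero(cplx.vedge_values <= eps)
    )
    F = int(np.count_nonzero(sub))
    chi = V - E + F
    return (b0, b0 - chi)


def betti_curve(diagram: PersistenceDiagram, thresholds: np.ndarray | None = None) -> BettiCurve:
    """Betti curves b_k(eps) = #{intervals with birth <= eps < death}."""
    if thresholds is None:
        thresholds = np.asarray(diagram.critical_values, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    counts = {0: np.zeros(len(thresholds), dtype=int), 1: np.zeros(len(thresholds), dtype=int)}
    for iv in diagram.intervals:
        counts[iv.dim] += (iv.birth <= thresholds) & (thresholds < iv.death)
    return BettiCurve(thresholds=thresholds, b0=counts[0], b1=counts[1])


def cap_infinite(diagram: PersistenceDiagram, policy: str = "cap_to_max") -> PersistenceDiagram:
    """Resolve essential (infinite-death) intervals before vectorization.

    ``cap_to_max`` sets their death to the global intensity maximum
    (idempotent); ``drop`` removes them.
    """
    if policy == "cap_to_max":
        new = tuple(
            replace(iv, death=diagram.vmax) if np.isinf(iv.death) else iv
            for iv in diagram.intervals
        )
        return replace(diagram, intervals=new)
    if policy == "drop":
        return replace(
            diagram, intervals=tuple(iv for iv in diagram.intervals if not iv.essential)
        )
    raise ValueError(f"unknown capping policy {policy!r}; expected 'cap_to_max' or 'drop'")
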