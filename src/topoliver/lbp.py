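"""Local binary pattern (P=8, R=1) histograms of persistence images.

Each interior pixel is encoded by thresholding its 8 neighbors against
the center: bit k is set iff neighbor_k >= center, neighbors enumerated
clockwise starting at the top-left corner.  Codes are binned either by
the u2 (uniform) mapping — the 58 patterns with at most two circular
0<->1 transitions get their own bin plus one catch-all, 59 bins — or by
riu2 (rotation-invariant uniform), where a uniform pattern is binned by
its number of set bits (10 bins).  Border pixels are excluded rather
than padded, so no fabricated codes enter the histogram.

The >= convention means constant regions map to code 255, and any
strictly increasing intensity transform leaves all codes unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LBPConfig", "FeatureVector", "lbp_code", "uniformity", "lbp_histogram"]

# clockwise from top-left, bit k = offset k
_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


@dataclass(frozen=True)
class LBPConfig:
    method: str = "u2"  # "u2" (59 bins) or "riu2" (10 bins)
    normalize: bool = True
    n_neighbors: int = 8
    radius: int = 1

    def __post_init__(self) -> None:
        if (self.n_neighbors, self.radius) != (8, 1):
            raise ValueError("only the P=8, R=1 operator is implemented")
        if self.method not in ("u2", "riu2"):
            raise ValueError(f"unknown LBP method {self.method!r}")


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.values)


def uniformity(code: int) -> int:
    """Number of circular 0<->1 transitions in the 8-bit pattern."""
    if not 0 <= code <= 255:
        raise ValueError(f"code {code} outside [0, 255]")
    bits = [(code >> k) & 1 for k in range(8)]
    return sum(bits[k] != bits[(k + 1) % 8] for k in range(8))


_UNIFORM_CODES: tuple[int, ...] = tuple(c for c in range(256) if uniformity(c) <= 2)  # 58 codes

# u2: uniform codes (ascending) -> 0..57, non-uniform -> 58
_U2_MAP = np.full(256, 58, dtype=np.intp)
for _i, _c in enumerate(_UNIFORM_CODES):
    _U2_MAP[_c] = _i
# riu2: uniform -> popcount (0..8), non-uniform -> 9
_RIU2_MAP = np.full(256, 9, dtype=np.intp)
for _c in _UNIFORM_CODES:
    _RIU2_MAP[_c] = int(bin(_c).count("1"))

_U2_NAMES = tuple(f"u2_{c:03d}" for c in _UNIFORM_CODES) + ("u2_nonuniform",)
_RIU2_NAMES = tuple(f"riu2_{k}" for k in range(9)) + ("riu2_nonuniform",)


def _code_image(image: np.ndarray) -> np.ndarray:
    """LBP codes of all interior pixels of a 2-D image, shape (r-2, c-2)."""
    center = image[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for k, (di, dj) in enumerate(_OFFSETS):
        nb = image[1 + di : image.shape[0] - 1 + di, 1 + dj : image.shape[1] - 1 + dj]
        codes |= (nb >= center).astype(np.int64) << k
    return codes


def lbp_code(image: np.ndarray, row: int, col: int) -> int:
    """LBP code of one interior pixel (bounds error on the border)."""
    image = np.asarray(image)
    r, c = image.shape
    if not (1 <= row < r - 1 and 1 <= col < c - 1):
        raise IndexError(f"({row}, {col}) is not an interior pixel of a {r}x{c} image")
    center = image[row, col]
    code = 0
    for k, (di, dj) in enumerate(_OFFSETS):
        if image[row + di, col + dj] >= center:
            code |= 1 << k
    return code


def lbp_histogram(image: np.ndarray, config: LBPConfig = LBPConfig()) -> FeatureVector:
    """Histogram of LBP codes over the interior pixels of ``image``."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError(f"image must be at least 3x3, got shape {image.shape}")
    codes = _code_image(image)
    if config.method == "u2":
        mapping, names, n_bins = _U2_MAP, _U2_NAMES, 59
    else:
        mapping, names, n_bins = _RIU2_MAP, _RIU2_NAMES, 10
    hist = np.bincount(mapping[codes.ravel()], minlength=n_bins).astype(float)
    if config.normalize:
        hist /= hist.sum()
    return FeatureVector(values=hist, names=names)
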