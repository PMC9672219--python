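"""Barcode, Betti-curve and persistence-image figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .homology import BettiCurve, PersistenceDiagram

__all__ = ["plot_barcode", "plot_betti_curve", "plot_persistence_image"]


def plot_barcode(diagram: PersistenceDiagram, ax=None, cap: float | None = None):
    """Horizontal bars per interval, H0 below H1; bar order has no meaning.

    Bars are sorted by (dim, birth, death); essential intervals extend
    to ``cap`` (default: the global intensity maximum).
    """
    if ax is None:
        _, ax = plt.subplots()
    cap = diagram.vmax if cap is None else cap
    ivs = sorted(diagram.intervals, key=lambda iv: (iv.dim, iv.birth, iv.death))
    for y, iv in enumerate(ivs):
        death = cap if np.isinf(iv.death) else iv.death
        ax.hlines(y, iv.birth, death, color="C0" if iv.dim == 0 else "C3", lw=1.5)
    ax.set_xlabel(r"$\varepsilon$ (intensity)")
    ax.set_ylabel("homology generators (display order)")
    return ax


def plot_betti_curve(curve: BettiCurve, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    ax.step(curve.thresholds, curve.b0, where="post", label=r"$b_0$")
    ax.step(curve.thresholds, curve.b1, where="post", label=r"$b_1$")
    ax.set_xlabel(r"$\varepsilon$ (intensity)")
    ax.set_ylabel("Betti number")
    ax.legend()
    return ax


def plot_persistence_image(pixels: np.ndarray, ax=None):
    """Persistence image with birth on x, persistence on y (origin at bottom)."""
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(pixels, origin="lower", aspect="auto", cmap="viridis")
    ax.set_xlabel("birth")
    ax.set_ylabel("persistence")
    plt.colorbar(im, ax=ax)
    return ax
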