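"""Barcode and characteristic-matrix plots.

Weighted barcodes are drawn as per-dimension panels (0-facets, 1-facets,
2-facets, …) with each bar colored by its Jones weight; the never-dying
final facet is drawn to the edge of the axis with an arrowhead.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .multiscale import CharacteristicMatrix
from .persistence import WeightedBarcode

__all__ = ["plot_barcode", "plot_matrix"]


def plot_barcode(
    B: WeightedBarcode,
    path=None,
    max_dimension: int | None = 2,
    cap_at_last_critical: bool = False,
):
    """Per-dimension weighted barcode panels; returns the matplotlib figure.

    With ``cap_at_last_critical`` the open-ended final bar is truncated at
    the largest critical value instead of drawn with an arrow.
    """
    kmax = B.max_dimension() if max_dimension is None else min(max_dimension, B.max_dimension())
    dims = [k for k in range(kmax + 1) if B.bars_of_dimension(k)]
    rmax = float(B.critical_values[-1]) if len(B.critical_values) else 1.0
    xlim = rmax * 1.1
    weights = [b.weight for b in B.bars if b.weight is not None]
    wlo, whi = (min(weights), max(weights)) if weights else (0.0, 1.0)
    if whi - wlo < 1e-12:
        wlo, whi = wlo - 0.5, whi + 0.5
    cmap = plt.get_cmap("coolwarm")
    norm = plt.Normalize(wlo, whi)

    fig, axes = plt.subplots(
        len(dims), 1, figsize=(7, 1.2 + 1.4 * len(dims)), sharex=True, squeeze=False
    )
    for ax, k in zip(axes[:, 0], dims):
        bars = sorted(B.bars_of_dimension(k), key=lambda b: (b.birth, b.death))
        for y, bar in enumerate(bars):
            color = "0.6" if bar.weight is None else cmap(norm(bar.weight))
            if math.isinf(bar.death):
                end = rmax if cap_at_last_critical else xlim
                ax.plot([bar.birth, end], [y, y], color=color, lw=2)
                if not cap_at_last_critical:
                    ax.annotate(
                        "", xy=(xlim, y), xytext=(end - 0.02 * xlim, y),
                        arrowprops=dict(arrowstyle="->", color=color),
                    )
            else:
                ax.plot([bar.birth, bar.death], [y, y], color=color, lw=2)
        ax.set_ylabel(f"{k}-facets")
        ax.set_ylim(-1, len(bars))
        ax.set_yticks([])
    axes[-1, 0].set_xlabel("Vietoris–Rips parameter r (Å)")
    axes[-1, 0].set_xlim(0, xlim)
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=norm)
    fig.colorbar(sm, ax=axes[:, 0], label=f"Jones weight at t={B.t:g}")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_matrix(M: CharacteristicMatrix, path=None):
    """Heatmap of a characteristic matrix (segments × shells)."""
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(M.values, aspect="auto", cmap="viridis", origin="lower")
    ax.set_xlabel("shell index")
    ax.set_ylabel("segment index")
    title = "normalized characteristic matrix" if M.normalized else "characteristic matrix"
    ax.set_title(f"{title} (t={M.t:g})")
    fig.colorbar(im, ax=ax)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
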