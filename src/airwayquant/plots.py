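"""QC figures: colocalization scatter maps and point-grid overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .io import DualChannelStack, SectionLabelMap
from .colocalization import coloc_map
from .stereology import PointGrid

__all__ = ["plot_coloc_map", "plot_grid_overlay"]


def plot_coloc_map(
    stack: DualChannelStack,
    threshold_green: float | None = None,
    threshold_red: float | None = None,
    path=None,
):
    """Joint-intensity scatter map: green marker on x, red (vitronectin) on y."""
    hist, _ = coloc_map(stack, threshold_green, threshold_red)
    fig, ax = plt.subplots(figsize=(4, 4))
    with np.errstate(divide="ignore"):
        ax.imshow(
            np.log10(hist.T + 1),
            origin="lower",
            cmap="inferno",
            extent=(0, 255, 0, 255),
            aspect="equal",
        )
    if threshold_green is not None:
        ax.axvline(threshold_green, color="w", lw=0.8, ls="--")
    if threshold_red is not None:
        ax.axhline(threshold_red, color="w", lw=0.8, ls="--")
    ax.set_xlabel("green intensity")
    ax.set_ylabel("red intensity")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_grid_overlay(labelmap: SectionLabelMap, grid: PointGrid, path=None):
    """Label map with the stereology test points overlaid."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(labelmap.labels, cmap="viridis", interpolation="nearest")
    ax.plot(grid.xs, grid.ys, "r+", markersize=6)
    ax.set_axis_off()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
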