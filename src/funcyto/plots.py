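"""Figure helpers: trace heatmaps, effect scatter plots, dendrogram heatmap.

All functions take an optional Matplotlib axis and return the axis, so they
compose into panels; a ``path`` argument saves straight to PNG/SVG with the
Agg backend (no display needed).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .clustering import Dendrogram
from .profiling import PopulationSplit
from .traces import TimestampSchedule


def trace_heatmap(
    data: pd.DataFrame,
    schedule: TimestampSchedule | None = None,
    ax=None,
    path=None,
    vmin: float | None = None,
    vmax: float | None = None,
    cmap: str = "viridis",
):
    """Cells x time color map of a trace matrix (columns become rows)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(
        data.to_numpy().T,
        aspect="auto",
        interpolation="nearest",
        cmap=cmap,
        vmin=vmin,
        vmax=vmax,
    )
    ax.set_xlabel("frame")
    ax.set_ylabel("cell (sorted)")
    plt.colorbar(im, ax=ax, label="R/R$_0$")
    if schedule is not None:
        for cond in schedule.conditions:
            ax.axvline(cond.start, color="w", lw=0.5)
            ax.text(cond.start, -1, cond.label, rotation=90, fontsize=6, va="bottom")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def effect_scatter(
    effects: pd.DataFrame,
    pair: tuple[str, str],
    split: PopulationSplit | None = None,
    ax=None,
    path=None,
):
    """Per-cell scatter of two conditions' amplitudes with LSQ fit lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    a, b = pair
    groups = (
        [("alpha_like", "tab:blue"), ("beta_like", "tab:red")]
        if split is not None
        else [(None, "tab:gray")]
    )
    for cls, color in groups:
        idx = effects.index if cls is None else split.cells(cls)
        x = effects.loc[idx, a].to_numpy(dtype=float)
        y = effects.loc[idx, b].to_numpy(dtype=float)
        ax.scatter(x, y, s=6, alpha=0.5, color=color, label=cls or "cells")
        if len(x) >= 2 and x.std() > 0:
            slope, intercept = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 2)
            ax.plot(xs, slope * xs + intercept, color=color, lw=1)
    ax.set_xlabel(a)
    ax.set_ylabel(b)
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def clustered_heatmap(
    effects: pd.DataFrame,
    cell_dendrogram: Dendrogram | None = None,
    condition_dendrogram: Dendrogram | None = None,
    path=None,
):
    """Z-scored effect heatmap with an optional condition dendrogram on top."""
    fig = plt.figure(figsize=(6, 6))
    if condition_dendrogram is not None:
        ax_top = fig.add_axes([0.1, 0.78, 0.8, 0.18])
        hierarchy.dendrogram(
            condition_dendrogram.linkage,
            labels=condition_dendrogram.items,
            ax=ax_top,
            color_threshold=0,
        )
        ax_top.set_xticklabels([])
        col_order = condition_dendrogram.leaf_order
    else:
        col_order = list(effects.columns)
    ax = fig.add_axes([0.1, 0.08, 0.8, 0.66])
    z = (effects - effects.mean(axis=1).to_numpy()[:, None]).div(
        effects.std(axis=1, ddof=0).replace(0, 1), axis=0
    )  # per-row z-score for display
    row_order = (
        cell_dendrogram.leaf_order if cell_dendrogram is not None else list(effects.index)
    )
    im = ax.imshow(
        z.loc[row_order, col_order].to_numpy(), aspect="auto", interpolation="nearest",
        cmap="RdBu_r", vmin=-2.5, vmax=2.5,
    )
    ax.set_xticks(range(len(col_order)))
    ax.set_xticklabels(col_order, rotation=90, fontsize=7)
    ax.set_ylabel("cell")
    plt.colorbar(im, ax=ax, label="z-score")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
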