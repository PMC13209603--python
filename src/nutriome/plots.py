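"""Figure helpers: clustered heatmap, paired diversity panels, PCoA.

Thin matplotlib wrappers around the analysis results; every function
returns the Axes (or figure) and optionally saves to PNG/SVG.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import ListedColormap

from .cohort import ClusterResult

__all__ = ["plot_label_heatmap", "plot_paired_metric", "plot_pcoa"]

# neutral / moderate / high
LABEL_COLORS = {"neutral": "#2e7d32", "moderate": "#f9a825", "high": "#c62828"}


def plot_label_heatmap(
    calls: pd.DataFrame,
    result: ClusterResult | None = None,
    path=None,
    colors: dict | None = None,
):
    """Samples x features heatmap of dysregulation labels
    (green/yellow/red), ordered by the clustering dendrograms."""
    colors = colors or LABEL_COLORS
    pivot = calls.pivot(index="sample_id", columns="feature_name", values="label")
    if result is not None:
        pivot = pivot.reindex(index=result.row_order)
        pivot = pivot.reindex(columns=[c for c in result.col_order if c in pivot])
    code_of = {"neutral": 0, "moderate": 1, "high": 2}
    codes = pivot.apply(lambda col: col.map(code_of)).astype(float)
    cmap = ListedColormap([colors["neutral"], colors["moderate"], colors["high"]])
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * pivot.shape[1]), max(4, 0.05 * pivot.shape[0]))
    )
    ax.pcolormesh(codes.to_numpy(), cmap=cmap, vmin=0, vmax=2)
    ax.set_xticks(np.arange(pivot.shape[1]) + 0.5)
    ax.set_xticklabels(pivot.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{pivot.shape[0]} samples")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax


def plot_paired_metric(per_pair: pd.DataFrame, metric: str = "", path=None):
    """Before/after boxes plus per-pair lines for one alpha metric."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(
        [per_pair["before"], per_pair["after"]], tick_labels=["Before", "After"]
    )
    for _, row in per_pair.iterrows():
        ax.plot([1, 2], [row["before"], row["after"]], color="grey", alpha=0.3, lw=0.5)
    ax.set_ylabel(metric or "diversity")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax


def plot_pcoa(coords: pd.DataFrame, explained, groups=None, path=None):
    """Scatter of the first two PCoA axes, colored by group."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    xs, ys = coords.iloc[:, 0], coords.iloc[:, 1]
    if groups is None:
        ax.scatter(xs, ys, s=12)
    else:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            mask = groups == g
            ax.scatter(xs[mask], ys[mask], s=12, label=str(g))
        ax.legend(frameon=False)
    ax.set_xlabel(f"PCo1 ({100 * explained[0]:.1f}%)")
    if len(explained) > 1:
        ax.set_ylabel(f"PCo2 ({100 * explained[1]:.1f}%)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
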