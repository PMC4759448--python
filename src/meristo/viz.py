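"""Matplotlib rendering of meristograms and PCA scatterplots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core import Meristogram, VARIABLES

CURVE_STYLE = {
    "L": dict(color="#1b9e77", marker="o"),
    "B": dict(color="#d95f02", marker="s"),
    "A": dict(color="#7570b3", marker="^"),
    "R": dict(color="#e7298a", marker="d"),
}


def plot_meristogram(m: Meristogram, ax=None, title: str | None = None):
    """Four curves against percent-position, both axes on the 0–100 percent
    scale."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    for v in VARIABLES:
        ax.plot(m.x, m.curve(v), label=v, markersize=3, linewidth=1.2, **CURVE_STYLE[v])
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 105)
    ax.set_xlabel("position (%)")
    ax.set_ylabel("percent-max-collection-value")
    ax.set_title(title or f"{m.label} (MAI {m.mai}%)")
    ax.legend(loc="lower center", ncol=4, fontsize=8)
    return ax


def save_meristogram_plot(m: Meristogram, path: str | Path) -> None:
    ax = plot_meristogram(m)
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)


def save_panel_plot(
    panels: Sequence[Sequence[Meristogram]],
    row_titles: Sequence[str],
    path: str | Path,
) -> None:
    """Grid of meristograms: one row per group (e.g. sex), one column per
    moving-average interval."""
    nrows = len(panels)
    ncols = max(len(row) for row in panels)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4.0 * ncols, 3.2 * nrows), squeeze=False
    )
    for i, row in enumerate(panels):
        for j in range(ncols):
            ax = axes[i][j]
            if j < len(row):
                m = row[j]
                plot_meristogram(m, ax=ax, title=f"{row_titles[i]} — MAI {m.mai}%")
            else:
                ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_pca_scatter(scores, variance_fraction, path: str | Path) -> None:
    """Scatter of the first two PC scores with labelled points."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(scores.iloc[:, 0], scores.iloc[:, 1], s=30, color="#333333")
    for label, (x, y) in scores.iloc[:, :2].iterrows():
        ax.annotate(label, (x, y), textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.set_xlabel(f"PC1 ({variance_fraction[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({variance_fraction[1] * 100:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
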