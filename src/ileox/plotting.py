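"""Report figures: community heatmap, type-frequency bars, index regression.

Plotting is a convenience layer over the results objects; every figure is
re-derivable from the archived tables.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .microbiome import CommunityTypingResults, relative_abundance


def community_heatmap(
    counts: pd.DataFrame,
    typing: CommunityTypingResults,
    top_n: int = 50,
    path: str | Path | None = None,
):
    """Heatmap of the most abundant phylotypes, samples ordered by type."""
    rel = relative_abundance(counts)
    top = rel.mean(axis=0).nlargest(min(top_n, rel.shape[1])).index
    order = typing.labels.sort_values().index
    mat = rel.loc[order, top].T
    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(np.log10(mat.values + 1e-5), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(top)))
    ax.set_yticklabels(top, fontsize=5)
    ax.set_xlabel("samples (grouped by community type)")
    fig.colorbar(im, ax=ax, label="log10 relative abundance")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def type_frequency_bars(freq: pd.DataFrame, path: str | Path | None = None):
    """Bar plot of posterior type frequencies by diet with credible intervals."""
    fig, ax = plt.subplots(figsize=(7, 4))
    diets = list(pd.unique(freq["diet"]))
    clusters = list(pd.unique(freq["cluster"]))
    width = 0.8 / len(diets)
    for i, diet in enumerate(diets):
        sub = freq[freq["diet"] == diet].set_index("cluster").loc[clusters]
        x = np.arange(len(clusters)) + i * width
        err = np.vstack(
            [sub["mean"] - sub["ci_2.5"], sub["ci_97.5"] - sub["mean"]]
        )
        ax.bar(x, sub["mean"], width=width, yerr=err, capsize=2, label=diet)
    ax.set_xticks(np.arange(len(clusters)) + 0.4)
    ax.set_xticklabels(clusters)
    ax.set_ylabel("relative frequency")
    ax.set_xlabel("community type")
    ax.legend()
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def index_regression_plot(
    index: pd.Series, log10_nt: pd.Series,
    slope: float, intercept: float,
    path: str | Path | None = None,
):
    """Scatter of log10 NT vs the anti-inflammatory index with the OLS line."""
    common = index.index.intersection(log10_nt.index)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(index.loc[common], log10_nt.loc[common], s=18)
    xs = np.linspace(index.loc[common].min(), index.loc[common].max(), 50)
    ax.plot(xs, intercept + slope * xs, color="crimson")
    ax.set_xlabel("anti-inflammatory index (summed SIVs)")
    ax.set_ylabel("NT content (log10 pixels/cell)")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
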