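"""Basic score and loading plots for fitted factor models."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import BiomarkerRanking

__all__ = ["score_plot", "loading_plot"]


def score_plot(scores: np.ndarray, groups=None, ax=None, title: str = "Sample scores"):
    """2D scatter of sample scores on two latent factors, colored by group."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be samples x 2")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    if groups is None:
        ax.scatter(scores[:, 0], scores[:, 1], s=25)
    else:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            sel = groups == g
            ax.scatter(scores[sel, 0], scores[sel, 1], s=25, label=str(g))
        ax.legend(frameon=False)
    ax.set_xlabel("latent factor 1")
    ax.set_ylabel("latent factor 2")
    ax.set_title(title)
    return ax


def loading_plot(ranking: BiomarkerRanking, ax=None):
    """Horizontal bar plot of signed loadings for a biomarker ranking."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.25 * len(ranking.table) + 1))
    tbl = ranking.table.iloc[::-1]
    colors = ["tab:red" if s < 0 else "tab:blue" for s in tbl["sign"]]
    ax.barh(tbl["feature"], tbl["loading"], color=colors)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel(f"loading on factor {ranking.factor + 1}")
    ax.set_title(f"top {ranking.k} {ranking.mode} features")
    return ax
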