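"""Loading-matrix panel plots for fitted models.

One panel per mode (electrode pair, stimulus, repetition), one line per
component, same colour across panels — the standard way of reading a
PARAFAC solution: pick a component's colour, read off which pairs,
which stimuli and which repetitions load on it.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .parafac import ParafacModel
from .pca import PcaModel

__all__ = ["plot_loadings", "plot_pca"]

_PANELS = (
    ("A", "electrode pair", "pair index"),
    ("B", "stimulus", "stimulus index"),
    ("C", "repetition", "repetition index"),
)


def plot_loadings(model: ParafacModel, title: str | None = None):
    """Three stacked panels of component loadings (pairs / stimuli /
    repetitions)."""
    fig, axes = plt.subplots(3, 1, figsize=(9, 8), constrained_layout=True)
    for ax, (attr, name, xlabel) in zip(axes, _PANELS):
        M = getattr(model, attr)
        x = np.arange(1, M.shape[0] + 1)
        for f in range(model.n_components):
            ax.plot(x, M[:, f], marker="o", ms=3, lw=1, label=f"component {f + 1}")
        ax.axhline(0.0, color="0.7", lw=0.5)
        ax.set_title(f"influence of the {name}", loc="left", fontsize=10)
        ax.set_xlabel(xlabel)
        ax.set_ylabel("loading")
    axes[0].legend(fontsize=8, ncol=min(model.n_components, 4))
    if title is None:
        title = (
            f"PARAFAC, F={model.n_components}, "
            f"{model.explained_variance_pct:.1f}% variance explained"
        )
    fig.suptitle(title)
    return fig


def plot_pca(model: PcaModel, n_components: int = 4, title: str | None = None):
    """Scores and loadings of the leading principal components."""
    n = min(n_components, model.rank)
    fig, axes = plt.subplots(2, 1, figsize=(9, 6), constrained_layout=True)
    for ax, M, name in (
        (axes[0], model.scores, "scores (observations)"),
        (axes[1], model.loadings, "loadings (variables)"),
    ):
        x = np.arange(1, M.shape[0] + 1)
        for f in range(n):
            pct = model.explained_variance_pct[f]
            ax.plot(x, M[:, f], lw=1, label=f"PC{f + 1} ({pct:.1f}%)")
        ax.axhline(0.0, color="0.7", lw=0.5)
        ax.set_title(name, loc="left", fontsize=10)
    axes[0].legend(fontsize=8, ncol=min(n, 4))
    fig.suptitle(title or f"PCA (mode-{model.mode} unfolding)")
    return fig
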