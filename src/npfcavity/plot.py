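"""Minimal plotting helpers: PCA score scatter and logo-style bar charts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .logos import LogoProfile
from .pca import PCAResult


def plot_pca_scores(
    p: PCAResult, assignment: pd.Series | None = None, ax=None
):
    """Scatter of PC1 vs PC2, optionally coloured by cluster assignment."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = p.scores.iloc[:, 0]
    y = p.scores.iloc[:, 1] if p.scores.shape[1] > 1 else 0 * x
    if assignment is not None:
        for cl in sorted(assignment.unique()):
            mask = assignment.reindex(p.scores.index) == cl
            ax.scatter(x[mask], y[mask], label=f"cluster {cl}", s=20)
        ax.legend(fontsize=8)
    else:
        ax.scatter(x, y, s=20)
    ev = p.explained_variance
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}%)")
    if len(ev) > 1:
        ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}%)")
    return ax


def plot_logo(profile: LogoProfile, ax=None, top: int = 3):
    """Information-content bar chart with the top residues lettered per position."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.2 * len(profile.information)), 2.5))
    positions = list(profile.information.index)
    ax.bar(range(len(positions)), profile.information.values, color="#888")
    for i, pos in enumerate(positions):
        row = profile.frequencies.loc[pos]
        if row.isna().all():
            continue
        best = row.nlargest(top)
        label = "".join(best.index[best > 0.2])
        if label:
            ax.text(i, profile.information[pos], label, ha="center", va="bottom", fontsize=6)
    ax.set_xticks(range(len(positions)))
    ax.set_xticklabels(positions, rotation=90, fontsize=6)
    ax.set_ylabel("bits")
    return ax
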