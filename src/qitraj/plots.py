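"""Diagnostic plots: trajectory spaghetti and fitted class-mean curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless backend; plots only ever go to files
import matplotlib.pyplot as plt
import numpy as np


def plot_spaghetti(Y, periods=None, ax=None, **line_kwargs):
    """All area trajectories as thin overlaid lines (variation overview)."""
    Y = np.asarray(Y)
    if periods is None:
        periods = np.arange(Y.shape[1])
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    kwargs = {"color": "steelblue", "alpha": 0.15, "lw": 0.7} | line_kwargs
    ax.plot(np.asarray(periods), Y.T, **kwargs)
    ax.set_xlabel("period")
    ax.set_ylabel("proportion")
    return ax


def plot_group_curves(Y, mixture, assignment, periods=None, ax=None):
    """Fitted class-mean curves over member trajectories colored by modal group."""
    Y = np.asarray(Y)
    if periods is None:
        periods = mixture.periods
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    cmap = plt.get_cmap("tab10")
    means = mixture.class_means
    for k in range(mixture.K):
        members = Y[assignment.modal == k]
        if len(members):
            ax.plot(periods, members.T, color=cmap(k), alpha=0.12, lw=0.6)
        label = assignment.names[k] if assignment.names else f"group {k}"
        ax.plot(periods, means[k], color=cmap(k), lw=2.5, label=label)
    ax.set_xlabel("period")
    ax.set_ylabel("proportion")
    ax.legend(fontsize=8)
    return ax


def save_fig(ax, path):
    ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(ax.figure)
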