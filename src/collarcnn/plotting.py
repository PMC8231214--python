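"""Diagnostic plots: confusion matrices, training history, pruning profile."""

from __future__ import annotations

import numpy as np

from .data_io import BehaviourLabel

__all__ = ["plot_confusion_matrix", "plot_history", "plot_prune_profile"]


def plot_confusion_matrix(report, normalised: bool = True, ax=None):
    """Heatmap of a :class:`~collarcnn.evaluation.MetricsReport` confusion
    matrix; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    matrix = report.confusion_normalised if normalised else report.confusion
    names = [c.name for c in BehaviourLabel][: matrix.shape[0]]
    im = ax.imshow(matrix, cmap="Blues", vmin=0, vmax=matrix.max() or 1)
    ax.set_xticks(range(len(names)), names, rotation=45, ha="right")
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fmt = "{:.2f}" if normalised else "{:d}"
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            ax.text(j, i, fmt.format(matrix[i, j]), ha="center", va="center",
                    color="white" if matrix[i, j] > 0.6 * (matrix.max() or 1) else "black")
    ax.figure.colorbar(im, ax=ax, fraction=0.046)
    ax.figure.tight_layout()
    return ax


def plot_history(history, ax=None):
    """Training/validation loss and learning rate per epoch."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(history["epoch"], history["train_loss"], label="train loss")
    ax.plot(history["epoch"], history["val_loss"], label="validation loss")
    ax.set_xlabel("epoch")
    ax.set_ylabel("cross-entropy")
    twin = ax.twinx()
    twin.plot(history["epoch"], history["lr"], color="grey", alpha=0.5, label="lr")
    twin.set_ylabel("learning rate")
    ax.legend(loc="upper right")
    ax.figure.tight_layout()
    return ax


def plot_prune_profile(trajectory, ax=None):
    """Cumulative sparsity versus pruning iteration, one line per stage."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    frame = trajectory.iterations
    for stage, group in frame.groupby("stage"):
        ax.plot(group["iteration"], group["sparsity"], marker=".", label=f"stage {stage}")
    ax.set_xlabel("pruning iteration (epoch)")
    ax.set_ylabel("cumulative sparsity")
    ax.set_ylim(0, 1)
    ax.legend()
    ax.figure.tight_layout()
    return ax
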