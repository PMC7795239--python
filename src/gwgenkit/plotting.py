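"""Plots: training curves, ROC curves, singular-value energies, node scores."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .dti.metrics import DTIMetrics
from .dti.nn import TrainingHistory
from .pnp import PNPResult


def plot_training_history(history: TrainingHistory, ax=None):
    """Loss and accuracy per epoch for the training and validation sets."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    epochs = np.arange(1, history.n_epochs + 1)
    ax.plot(epochs, history.train_loss, label="training loss")
    ax.plot(epochs, history.val_loss, label="validation loss")
    ax2 = ax.twinx()
    ax2.plot(epochs, history.train_accuracy, "--", label="training accuracy")
    ax2.plot(epochs, history.val_accuracy, "--", label="validation accuracy")
    ax.set_xlabel("epoch")
    ax.set_ylabel("binary cross-entropy")
    ax2.set_ylabel("accuracy")
    if history.best_epoch is not None:
        ax.axvline(history.best_epoch + 1, color="grey", lw=0.8, ls=":")
    ax.legend(loc="upper right", fontsize=8)
    ax2.legend(loc="lower right", fontsize=8)
    return ax


def plot_roc(metrics: DTIMetrics, label: str = "DTI model", ax=None):
    """ROC curve with the AUC in the legend; diagonal = random classifier."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(metrics.roc_fpr, metrics.roc_tpr, label=f"{label} (area = {metrics.auc:.3f})")
    ax.plot([0, 1], [0, 1], ":", color="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    return ax


def plot_energies(pnp: PNPResult, threshold: float = 0.85, ax=None):
    """Cumulative singular-value energy with the retention threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    cum = np.cumsum(pnp.energies)
    ax.step(np.arange(1, len(cum) + 1), cum, where="post")
    ax.axhline(threshold, color="red", lw=0.8, ls="--")
    if pnp.n_retained is not None:
        ax.axvline(pnp.n_retained, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("singular vectors retained")
    ax.set_ylabel("cumulative energy")
    ax.set_ylim(0, 1.02)
    return ax


def plot_scores(scores: dict[str, float], top: int = 30, ax=None):
    """Horizontal bar chart of the top projection scores."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.25 * top + 1))
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    names = [k for k, _ in ranked][::-1]
    vals = [v for _, v in ranked][::-1]
    ax.barh(names, vals)
    ax.set_xlabel("projection score")
    return ax
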