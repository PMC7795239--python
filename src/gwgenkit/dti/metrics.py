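"""Classification metrics: confusion counts, TPR/specificity/FPR, ROC, AUC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve

from .nn import binary_cross_entropy


@dataclass
class DTIMetrics:
    """Threshold-0.5 confusion statistics plus the full ROC curve and AUC."""

    tp: int
    tn: int
    fp: int
    fn: int
    tpr: float
    specificity: float
    fpr: float
    accuracy: float
    loss: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float


def evaluate(scores: np.ndarray, labels: np.ndarray) -> DTIMetrics:
    """Evaluate predicted probabilities against binary labels.

    The confusion matrix is taken at threshold 0.5; the ROC curve sweeps
    every unique score and the AUC is its trapezoidal area.  A single-class
    label vector leaves the ROC undefined and raises.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    pred = scores >= 0.5
    pos, neg = labels == 1, labels == 0
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & neg))
    fp = int(np.sum(pred & neg))
    fn = int(np.sum(~pred & pos))
    tpr = tp / (tp + fn)
    specificity = tn / (tn + fp)
    fpr_curve, tpr_curve, _ = roc_curve(labels, scores)
    return DTIMetrics(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        tpr=tpr,
        specificity=specificity,
        fpr=1.0 - specificity,
        accuracy=(tp + tn) / labels.shape[0],
        loss=binary_cross_entropy(np.clip(scores, 0.0, 1.0), labels),
        roc_fpr=fpr_curve,
        roc_tpr=tpr_curve,
        auc=float(_auc(fpr_curve, tpr_curve)),
    )
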