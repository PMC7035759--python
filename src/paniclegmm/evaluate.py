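"""Pixel-level evaluation against manually labelled masks.

Panicle is the positive class.  Since ground truth distinguishes only
panicle from non-panicle, all non-panicle components are collapsed before
comparison.  ROC curves are traced by sweeping the panicle posterior
threshold; curves from several images are averaged pointwise at matched
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import threshold_classify

__all__ = ["ConfusionCounts", "Metrics", "RocCurve", "confusion", "metrics",
           "roc_sweep", "average_curves"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class Metrics:
    """Recall/precision/F1 and ROC coordinates; undefined values are None."""

    recall: float | None
    precision: float | None
    f1: float | None
    tpr: float | None
    fpr: float | None


@dataclass
class RocCurve:
    """One ROC trace: thresholds decreasing, (fpr, tpr) per threshold."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """2x2 counts of a predicted vs a true panicle mask."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Recall, precision, F1, TPR and FPR from confusion counts.

    A metric whose denominator is zero is reported as None (absent), never
    coerced to 0.
    """
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else None
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else None
    if recall is not None and precision is not None and precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    elif recall is not None and precision is not None:
        f1 = 0.0
    else:
        f1 = None
    fpr = c.fp / (c.fp + c.tn) if c.fp + c.tn > 0 else None
    return Metrics(recall=recall, precision=precision, f1=f1,
                   tpr=recall, fpr=fpr)


def roc_sweep(posteriors: np.ndarray, c: int, truth: np.ndarray,
              thresholds: np.ndarray | None = None) -> RocCurve:
    """ROC curve by sweeping the panicle posterior threshold.

    ``thresholds`` must be sorted decreasing (default: 101 points from 1
    to 0), so TPR and FPR are non-decreasing along the curve.
    """
    if thresholds is None:
        thresholds = np.linspace(1.0, 0.0, 101)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) > 0):
        raise ValueError("thresholds must be sorted in decreasing order")
    tpr = np.empty(thresholds.shape[0])
    fpr = np.empty(thresholds.shape[0])
    for i, t in enumerate(thresholds):
        m = metrics(confusion(threshold_classify(posteriors, c, t), truth))
        tpr[i] = np.nan if m.tpr is None else m.tpr
        fpr[i] = np.nan if m.fpr is None else m.fpr
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr)


def average_curves(curves: list[RocCurve]) -> RocCurve:
    """Pointwise mean of TPR and FPR over curves on a shared threshold grid."""
    if not curves:
        raise ValueError("need at least one curve")
    grid = curves[0].thresholds
    for c in curves[1:]:
        if c.thresholds.shape != grid.shape or not np.allclose(c.thresholds,
                                                               grid):
            raise ValueError("curves must share the same threshold grid")
    return RocCurve(
        thresholds=grid.copy(),
        tpr=np.mean([c.tpr for c in curves], axis=0),
        fpr=np.mean([c.fpr for c in curves], axis=0),
    )
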