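"""Segmentation evaluation metrics and the binary focal loss.

Pixel-level precision, recall, F1 and IoU are computed from confusion
counts with foreground (1) as the positive class.  F1 and IoU satisfy the
identity ``F1 = 2*IoU / (1 + IoU)`` whenever both come from the same
counts.

Degenerate-case convention: any 0/0 ratio is defined as 0, except when the
predicted and reference masks are both entirely empty, in which case the
comparison is a vacuous success and every metric is 1.  Reference masks
are never empty in normal operation; the convention only matters for
edge-case robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "FocalLossParams",
    "confusion_counts",
    "metric_report",
    "binary_focal_loss",
    "binarize",
]

#: probabilities are clipped to [EPS, 1-EPS] before any log is taken
EPS = 1e-7


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a predicted mask against a reference mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """Precision, recall, F1 and IoU derived from one set of counts."""

    precision: float
    recall: float
    f1: float
    iou: float


@dataclass(frozen=True)
class FocalLossParams:
    """Parameters of the binary focal loss.

    alpha : float
        Class-balance weight on the foreground term, in (0, 1].
    gamma : float
        Focusing exponent >= 0; ``gamma=0`` recovers (alpha-weighted)
        binary cross-entropy.
    beta : float
        Inert parameter, carried for configuration completeness; it does
        not enter the loss.
    """

    alpha: float = 0.25
    gamma: float = 2.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/FN/TN between two aligned binary masks."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metric_report(counts: ConfusionCounts) -> MetricReport:
    """Precision, recall, F1, IoU from confusion counts.

    ``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)``, F1 is their
    harmonic mean and ``IoU = TP/(TP+FN+FP)``.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp == 0 and fp == 0 and fn == 0:
        # both rasters entirely empty: vacuously perfect agreement
        return MetricReport(precision=1.0, recall=1.0, f1=1.0, iou=1.0)

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    f1 = ratio(2.0 * precision * recall, precision + recall)
    iou = ratio(tp, tp + fn + fp)
    return MetricReport(precision=precision, recall=recall, f1=f1, iou=iou)


def compare_masks(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    """Convenience: metric report directly from two masks."""
    return metric_report(confusion_counts(pred, truth))


def binary_focal_loss(
    truth: np.ndarray,
    pred: np.ndarray,
    params: FocalLossParams | None = None,
) -> float:
    """Mean binary focal loss of a probability map against a binary mask.

    Per pixel::

        L = -alpha * y * (1-p)**gamma * log(p)
            - (1-alpha) * (1-y) * p**gamma * log(1-p)

    with ``y`` the ground-truth label and ``p`` the predicted foreground
    probability.  The modulating factors ``(1-p)**gamma`` / ``p**gamma``
    down-weight pixels the model already classifies confidently, focusing
    the gradient on hard pixels.  Reduction is the mean over pixels, so
    the value is resolution-independent.
    """
    if params is None:
        params = FocalLossParams()
    y = _as_binary(truth, "truth").astype(np.float64)
    p = np.asarray(pred, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: truth {y.shape} vs pred {p.shape}")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    p = np.clip(p, EPS, 1.0 - EPS)
    a, g = params.alpha, params.gamma
    loss = -a * y * (1.0 - p) ** g * np.log(p) - (1.0 - a) * (1.0 - y) * p ** g * np.log1p(-p)
    return float(loss.mean())


def binarize(pred: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a 0/1 mask (``p >= threshold``)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    p = np.asarray(pred, dtype=np.float64)
    return (p >= threshold).astype(np.uint8)
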