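"""Pixel-level segmentation metrics.

Predictions and references are binary masks over the same grid; foreground
(vessel) pixels are 1.  From the pixel confusion counts we derive

* IoU (Jaccard): ``TP / (TP + FP + FN)``,
* precision ``TP / (TP + FP)`` and recall ``TP / (TP + FN)``,
* F1 (Dice): the harmonic mean ``2PR / (P + R)``.

Dataset-level aggregation averages IoU, precision and recall per image and
derives the dataset F1 from the aggregated precision and recall.  (This is
the convention under which a published table's F1 column equals the
harmonic mean of its precision and recall columns while its IoU column is
a separate per-image average; micro-averaging over pooled pixel counts is
available separately via a mosaic of the inputs.)

Degenerate cases are defined so that metrics stay meaningful on empty
tiles: an empty prediction against an empty reference scores 1.0
everywhere; an empty denominator with a non-empty counterpart scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "iou",
           "precision_recall", "f1", "evaluate_pair", "evaluate_dataset"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    iou: float
    precision: float
    recall: float
    f1: float


def _as_binary(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask must be binary (0/1), found values {vals[:5]}")
    return arr.astype(bool)


def confusion(pred, mask) -> ConfusionCounts:
    """Pixel confusion counts between predicted and reference masks."""
    p = _as_binary(pred)
    m = _as_binary(mask)
    if p.shape != m.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs mask {m.shape}")
    tp = int(np.count_nonzero(p & m))
    fp = int(np.count_nonzero(p & ~m))
    fn = int(np.count_nonzero(~p & m))
    tn = int(np.count_nonzero(~p & ~m))
    return ConfusionCounts(tp, fp, fn, tn)


def iou(counts: ConfusionCounts) -> float:
    """Jaccard index |pred ∩ mask| / |pred ∪ mask|; 1.0 when both are empty."""
    union = counts.tp + counts.fp + counts.fn
    if union == 0:
        return 1.0
    return counts.tp / union


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    if counts.tp + counts.fp + counts.fn == 0:
        return 1.0, 1.0  # both masks empty: the (empty) prediction is correct
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return precision, recall


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate_pair(pred, mask) -> MetricReport:
    counts = confusion(pred, mask)
    p, r = precision_recall(counts)
    return MetricReport(iou=iou(counts), precision=p, recall=r, f1=f1(p, r))


def evaluate_dataset(predictions: Sequence, references: Sequence) -> MetricReport:
    """Per-image averaged IoU/precision/recall; F1 from the averaged P and R."""
    preds = list(predictions)
    refs = list(references)
    if len(preds) != len(refs):
        raise ValueError("predictions and references differ in length")
    if not preds:
        raise ValueError("empty dataset")
    reports = [evaluate_pair(p, m) for p, m in zip(preds, refs)]
    mean_iou = float(np.mean([r.iou for r in reports]))
    mean_p = float(np.mean([r.precision for r in reports]))
    mean_r = float(np.mean([r.recall for r in reports]))
    return MetricReport(iou=mean_iou, precision=mean_p, recall=mean_r,
                        f1=f1(mean_p, mean_r))


def evaluate_micro(predictions: Sequence, references: Sequence) -> MetricReport:
    """Micro-average: pool all pixels (equivalent to one big mosaic)."""
    counts = [confusion(p, m) for p, m in zip(predictions, references)]
    pooled = ConfusionCounts(sum(c.tp for c in counts), sum(c.fp for c in counts),
                             sum(c.fn for c in counts), sum(c.tn for c in counts))
    p, r = precision_recall(pooled)
    return MetricReport(iou=iou(pooled), precision=p, recall=r, f1=f1(p, r))
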