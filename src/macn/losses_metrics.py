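"""Cross-entropy / focal losses and the confusion-count metric suite.

The losses operate on per-pixel foreground probabilities p and binary
labels y, through the probability of the true class

    pt = p        if y = 1
    pt = 1 - p    if y = 0

Cross-entropy is the mean of -log(pt); the focal loss multiplies each
pixel's term by (1 - pt)^gamma, down-weighting easily classified pixels —
at pt = 0.9 and gamma = 2 a pixel contributes 100× less than under
cross-entropy. gamma = 0 recovers cross-entropy exactly.

Metrics are the usual pixelwise confusion counts and

    P = TP/(TP+FP)   R = TP/(TP+FN)
    F1 = 2PR/(P+R)   IoU = TP/(TP+FP+FN) = F1/(2-F1)

TN-based scores are deliberately absent: with heavy class imbalance they
are uninformative. Dataset-level scores are micro-averaged (counts pooled
over patches before division); macro-averaging is available separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7  # probability clamp before the log

__all__ = ["LossConfig", "SegMetrics", "cross_entropy", "focal_loss",
           "confusion_counts", "compute_metrics", "macro_average"]


@dataclass(frozen=True)
class LossConfig:
    kind: str = "focal"          # "focal" | "cross_entropy"
    gamma: float = 1.0
    class_weights: tuple[float, float] | None = None  # (background, foreground)

    def __post_init__(self):
        if self.kind not in ("focal", "cross_entropy"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.gamma < 0:
            raise ValueError("gamma must be ≥ 0")


def _true_class_prob(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    pt = np.where(y == 1, p, 1.0 - p)
    return np.clip(pt, EPS, 1.0)


def cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy -log(pt) over all pixels."""
    return float(np.mean(-np.log(_true_class_prob(p, y))))


def focal_loss(p: np.ndarray, y: np.ndarray, gamma: float = 1.0) -> float:
    """Mean focal loss (1-pt)^gamma * (-log pt); gamma=0 is cross-entropy."""
    if gamma < 0:
        raise ValueError("gamma must be ≥ 0")
    pt = _true_class_prob(p, y)
    return float(np.mean((1.0 - pt) ** gamma * (-np.log(pt))))


def confusion_counts(pred_mask: np.ndarray, gt_mask: np.ndarray,
                     ) -> tuple[int, int, int, int]:
    """Pixelwise (TP, FP, FN, TN) of a binary prediction against ground
    truth; positive = foreground (duct)."""
    pred = np.asarray(pred_mask).astype(bool)
    gt = np.asarray(gt_mask).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return tp, fp, fn, tn


@dataclass
class SegMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    iou: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1, "iou": self.iou, "degenerate": self.degenerate}


def compute_metrics(counts: tuple[int, int, int, int],
                    empty_agreement: bool = False) -> SegMetrics:
    """Precision/recall/F1/IoU from (TP, FP, FN, TN) counts.

    Zero denominators yield 0 and set ``degenerate``; under
    ``empty_agreement`` an empty prediction of an empty ground truth
    scores 1 instead.
    """
    tp, fp, fn, tn = (int(c) for c in counts)
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be nonnegative")
    degenerate = False

    def ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 1.0 if empty_agreement and tp + fp + fn == 0 else 0.0
        return num / den

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    f1 = ratio(2 * precision * recall,
               precision + recall) if (precision + recall) > 0 else ratio(0, 0)
    iou = ratio(tp, tp + fp + fn)
    return SegMetrics(tp, fp, fn, tn, precision, recall, f1, iou, degenerate)


def macro_average(per_patch: list[SegMetrics]) -> dict:
    """Unweighted mean of per-patch scores (macro averaging)."""
    if not per_patch:
        raise ValueError("no metrics to average")
    return {k: float(np.mean([getattr(m, k) for m in per_patch]))
            for k in ("precision", "recall", "f1", "iou")}
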