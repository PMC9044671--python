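"""Segmentation evaluation: confusion matrix, IoU/mIoU, precision, recall, F1.

The cotton-boll class is the positive class throughout.  With TP/FP/FN/TN
pixel counts,

    IoU    = TP / (TP + FP + FN)
    CPA    = TP / (TP + FP)          (class pixel accuracy == precision)
    Recall = TP / (TP + FN)
    F1     = 2 * CPA * Recall / (CPA + Recall)
    mIoU   = mean of per-class IoU over the k + 1 classes (here 2)

Degenerate denominators (no positives predicted or present) yield 0 with a
warning rather than NaN.  Dataset-level reports come in two aggregation
modes: ``pooled`` sums confusion counts over images before applying the
formulas; ``per_image_mean`` averages per-image metric values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "RSquared",
    "confusion",
    "background_confusion",
    "iou",
    "cpa",
    "recall",
    "f1",
    "miou",
    "r_squared",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class ConfusionMatrix:
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

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class MetricReport:
    iou_per_class: tuple[float, float]  # (background, cotton)
    miou: float
    cpa: float  # positive-class precision
    recall: float
    f1: float
    k: int = 1  # classes are 0..k


@dataclass(frozen=True)
class RSquared:
    r2: float


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    bad = np.setdiff1d(np.unique(arr), [0, 1])
    if bad.size:
        raise ValueError(f"{name} is not binary; offending values: {bad.tolist()}")
    return arr.astype(bool)


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionMatrix:
    """Pixel-wise confusion counts with cotton (1) as the positive class."""
    pred = _check_binary(pred_mask, "pred_mask")
    true = _check_binary(true_mask, "true_mask")
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs true {true.shape}")
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    tn = int((~pred & ~true).sum())
    return ConfusionMatrix(tp, fp, fn, tn)


def background_confusion(cm: ConfusionMatrix) -> ConfusionMatrix:
    """The same counts with background treated as the positive class."""
    return ConfusionMatrix(tp=cm.tn, fp=cm.fn, fn=cm.fp, tn=cm.tp)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"degenerate denominator in {what}; returning 0", stacklevel=3)
        return 0.0
    return num / den


def iou(cm: ConfusionMatrix) -> float:
    return _safe_div(cm.tp, cm.tp + cm.fp + cm.fn, "IoU")


def cpa(cm: ConfusionMatrix) -> float:
    return _safe_div(cm.tp, cm.tp + cm.fp, "CPA")


def recall(cm: ConfusionMatrix) -> float:
    return _safe_div(cm.tp, cm.tp + cm.fn, "recall")


def f1(cpa_val: float, recall_val: float) -> float:
    return _safe_div(2.0 * cpa_val * recall_val, cpa_val + recall_val, "F1")


def miou(cms: Sequence[ConfusionMatrix]) -> float:
    """Mean IoU over per-class confusion matrices (k + 1 classes)."""
    if len(cms) == 0:
        raise ValueError("need at least one per-class confusion matrix")
    return float(np.mean([iou(cm) for cm in cms]))


def r_squared(t: Sequence[float], c: Sequence[float]) -> RSquared:
    """Coefficient of determination between model values t and measured c.

    ``r2 = 1 - sum((t_i - c_i)^2) / sum((t_i - mean(c))^2)``; exactly 1 when
    t equals c elementwise.  Raises when the denominator vanishes (model
    values all equal to the measured mean) or on a length mismatch.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if t.shape != c.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {c.shape}")
    if t.size < 2:
        raise ValueError("need at least two points")
    denom = float(((t - c.mean()) ** 2).sum())
    if denom == 0.0:
        raise ValueError("degenerate variance: model values all equal the measured mean")
    return RSquared(r2=1.0 - float(((t - c) ** 2).sum()) / denom)


def _report_from_cm(cm: ConfusionMatrix) -> MetricReport:
    bg = background_confusion(cm)
    iou_fg, iou_bg = iou(cm), iou(bg)
    p, r = cpa(cm), recall(cm)
    return MetricReport(
        iou_per_class=(iou_bg, iou_fg),
        miou=miou([bg, cm]),
        cpa=p,
        recall=r,
        f1=f1(p, r),
    )


def evaluate_dataset(
    predictions: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    mode: str = "per_image_mean",
) -> MetricReport:
    """Dataset-level metric report over paired prediction/truth masks."""
    if len(predictions) == 0 or len(predictions) != len(truths):
        raise ValueError("need a non-empty, equal-length set of prediction/truth pairs")
    cms = [confusion(p, t) for p, t in zip(predictions, truths)]
    if mode == "pooled":
        total = cms[0]
        for cm in cms[1:]:
            total = total + cm
        return _report_from_cm(total)
    if mode == "per_image_mean":
        reports = [_report_from_cm(cm) for cm in cms]
        return MetricReport(
            iou_per_class=(
                float(np.mean([r.iou_per_class[0] for r in reports])),
                float(np.mean([r.iou_per_class[1] for r in reports])),
            ),
            miou=float(np.mean([r.miou for r in reports])),
            cpa=float(np.mean([r.cpa for r in reports])),
            recall=float(np.mean([r.recall for r in reports])),
            f1=float(np.mean([r.f1 for r in reports])),
        )
    raise ValueError(f"unknown mode {mode!r}; use 'pooled' or 'per_image_mean'")
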