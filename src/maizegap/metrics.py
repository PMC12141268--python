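"""Detection and count-regression metrics.

Single-class detector scoring: greedy IoU matching at a fixed threshold
(0.5 by default), precision / recall / F1 from the TP-FP-FN counts, and
average precision as the all-points interpolated area under the
precision-envelope vs recall curve (for one class, mAP equals AP).
Count predictions against manual counts are scored with R^2, RMSE and MAE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectionBox",
    "MatchResult",
    "iou",
    "match_boxes",
    "precision_recall_f1",
    "average_precision",
    "ap_from_scored_flags",
    "mean_average_precision",
    "regression_metrics",
]


@dataclass(frozen=True)
class DetectionBox:
    """Axis-aligned box in pixels with an optional confidence score."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: float = 1.0
    label: str = "maize"

    def __post_init__(self):
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("box must have positive width and height")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def center(self) -> tuple[float, float]:
        return (self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0


def iou(a: DetectionBox, b: DetectionBox) -> float:
    """Intersection-over-union of two boxes."""
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (pred idx, truth idx, IoU)
    # per-prediction TP flags in descending-score order, for PR curves
    pred_order: list[int] = field(default_factory=list)
    pred_is_tp: list[bool] = field(default_factory=list)


def match_boxes(
    preds: list[DetectionBox],
    truths: list[DetectionBox],
    iou_thr: float = 0.5,
) -> MatchResult:
    """Greedy score-ordered matching of predictions to ground truth.

    Predictions are visited in descending score order (stable for ties);
    each claims the unmatched truth with the highest IoU if that IoU
    reaches the threshold, otherwise it is a false positive. Unclaimed
    truths are false negatives.
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    matched = [False] * len(truths)
    pairs: list[tuple[int, int, float]] = []
    is_tp: list[bool] = []
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(truths):
            if matched[j]:
                continue
            v = iou(preds[i], t)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_thr:
            matched[best_j] = True
            pairs.append((i, best_j, best_iou))
            is_tp.append(True)
        else:
            is_tp.append(False)
    tp = sum(is_tp)
    return MatchResult(
        tp=tp,
        fp=len(preds) - tp,
        fn=len(truths) - tp,
        pairs=pairs,
        pred_order=order,
        pred_is_tp=is_tp,
    )


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = harmonic mean; zeros when undefined."""
    p = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else 0.0
    r = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def _pr_curve(scores: np.ndarray, flags: np.ndarray, n_truth: int):
    order = np.argsort(-scores, kind="stable")
    tp_cum = np.cumsum(flags[order])
    fp_cum = np.cumsum(~flags[order])
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    return recall, precision


def average_precision(
    preds: list[DetectionBox],
    truths: list[DetectionBox],
    iou_thr: float = 0.5,
    _match: MatchResult | None = None,
) -> float:
    """All-points interpolated AP for one image's scored predictions.

    The precision envelope (running max from the right) is integrated over
    recall. Raises ``ValueError`` when there is no ground truth.
    """
    if len(truths) == 0:
        raise ValueError("no ground truth; AP undefined")
    if len(preds) == 0:
        return 0.0
    m = _match or match_boxes(preds, truths, iou_thr)
    scores = np.array([preds[i].score for i in m.pred_order])
    flags = np.array(m.pred_is_tp, dtype=bool)
    return ap_from_scored_flags(scores, flags, len(truths))


def ap_from_scored_flags(scores: np.ndarray, is_tp: np.ndarray, n_truth: int) -> float:
    """AP from pooled (score, TP?) detections and a ground-truth total."""
    if n_truth <= 0:
        raise ValueError("no ground truth; AP undefined")
    scores = np.asarray(scores, dtype=float)
    is_tp = np.asarray(is_tp, dtype=bool)
    if scores.size == 0:
        return 0.0
    recall, precision = _pr_curve(scores, is_tp, n_truth)
    return _ap_from_curve(recall, precision)


def _ap_from_curve(recall: np.ndarray, precision: np.ndarray) -> float:
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[0.0], precision, [0.0]])
    # monotone precision envelope from the right
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.where(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def mean_average_precision(ap_per_class: dict[str, float]) -> float:
    """mAP = mean of per-class APs (equals AP for a single class)."""
    if not ap_per_class:
        raise ValueError("no classes")
    return float(np.mean(list(ap_per_class.values())))


def regression_metrics(predicted, actual) -> tuple[float, float, float]:
    """R^2, RMSE and MAE of count predictions against reference counts.

    R^2 = 1 - SS_res / SS_tot. When the reference counts have zero
    variance R^2 is undefined: NaN is returned with a warning.
    """
    pred = np.asarray(predicted, dtype=float).ravel()
    act = np.asarray(actual, dtype=float).ravel()
    if pred.size != act.size or pred.size < 2:
        raise ValueError("predicted and actual must have equal length >= 2")
    resid = act - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((act - act.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("reference counts have zero variance; R^2 undefined", stacklevel=2)
        return float("nan"), rmse, mae
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return r2, rmse, mae
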