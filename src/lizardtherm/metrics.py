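"""Object-detection evaluation: IoU, confusion counts, P/R/F1, AP and mAP.

Standard detection metrics over the seven annotated classes.  Matching is
greedy in confidence order (the YOLO-ecosystem convention): within each
class, predictions sorted by descending confidence each claim the unmatched
ground-truth box of highest IoU, provided that IoU reaches the threshold
(default 0.50).  Average precision integrates the precision envelope over
recall with all-point interpolation.

TN is carried in :class:`ConfusionCounts` for completeness but is always 0
in detection — there is no meaningful "correctly predicted absence" box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .detection import ClassLabel, Detection
from .frame_io import Rect

__all__ = [
    "ConfusionCounts",
    "PRPoint",
    "iou",
    "match_detections",
    "precision_recall_f1",
    "pr_curve",
    "average_precision",
    "mean_average_precision",
    "evaluate",
]

DEFAULT_IOU_THRESHOLD = 0.50
COCO_IOU_THRESHOLDS = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0  # kept for completeness; always 0 in detection

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class PRPoint:
    recall: float
    precision: float
    threshold: float = 0.0

    def __post_init__(self):
        for name in ("recall", "precision", "threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def iou(a: Rect, b: Rect) -> float:
    """Intersection over union of two pixel rectangles; 0 when disjoint."""
    ix = max(0, min(a.x2, b.x2) - max(a.x, b.x))
    iy = max(0, min(a.y2, b.y2) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


GroundTruth = tuple[ClassLabel, Rect]


def _greedy_match(
    preds: Sequence[Detection],
    gt_boxes: Sequence[Rect],
    iou_threshold: float,
) -> list[int | None]:
    """For confidence-sorted same-class preds, the index of the gt each claims."""
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    claimed: set[int] = set()
    assignment: list[int | None] = [None] * len(preds)
    for i in order:
        best_j, best_iou = None, iou_threshold
        for j, gt in enumerate(gt_boxes):
            if j in claimed:
                continue
            v = iou(preds[i].box, gt)
            if v >= best_iou and (best_j is None or v > best_iou):
                best_j, best_iou = j, v
        if best_j is not None:
            claimed.add(best_j)
            assignment[i] = best_j
    return assignment


def match_detections(
    preds: Sequence[Detection],
    gts: Sequence[GroundTruth],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> ConfusionCounts:
    """Confusion counts over all classes at one IoU threshold.

    Per class: predictions in descending confidence each match the
    unmatched same-class ground truth with highest IoU when that IoU
    reaches the threshold (TP), otherwise they count as FP; leftover
    ground truths are FN.  Always tp + fp == len(preds) and
    tp + fn == len(gts).
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must be in [0, 1], got {iou_threshold}")
    counts = ConfusionCounts()
    labels = {d.label for d in preds} | {lbl for lbl, _ in gts}
    for label in labels:
        cls_preds = [d for d in preds if d.label == label]
        cls_gts = [r for lbl, r in gts if lbl == label]
        assignment = _greedy_match(cls_preds, cls_gts, iou_threshold)
        tp = sum(1 for a in assignment if a is not None)
        counts = counts + ConfusionCounts(
            tp=tp, fp=len(cls_preds) - tp, fn=len(cls_gts) - tp
        )
    return counts


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float, bool]:
    """(precision, recall, F1, degenerate_flag).

    Zero denominators yield 0 for the affected metric and set the flag.
    """
    degenerate = False
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision, degenerate = 0.0, True
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        degenerate = degenerate or c.tp + c.fp + c.fn > 0
    return precision, recall, f1, degenerate


def pr_curve(
    preds: Sequence[Detection],
    gts: Sequence[GroundTruth],
    label: ClassLabel,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> list[PRPoint]:
    """Precision-recall points for one class, one per prediction rank.

    Predictions are swept in descending confidence; each rank contributes
    the cumulative precision and recall after admitting that prediction.
    """
    cls_preds = sorted(
        (d for d in preds if d.label == label), key=lambda d: -d.confidence
    )
    cls_gts = [r for lbl, r in gts if lbl == label]
    n_gt = len(cls_gts)
    assignment = _greedy_match(cls_preds, cls_gts, iou_threshold)
    points = []
    tp = 0
    for rank, (det, a) in enumerate(zip(cls_preds, assignment), start=1):
        if a is not None:
            tp += 1
        points.append(
            PRPoint(
                recall=tp / n_gt if n_gt else 0.0,
                precision=tp / rank,
                threshold=det.confidence,
            )
        )
    return points


def average_precision(points: Sequence[PRPoint]) -> float:
    """Area under the PR curve with all-point interpolation.

    The precision envelope p_env(r) = max{p_i : r_i >= r} is integrated
    over recall in [0, 1]; beyond the largest achieved recall the envelope
    is 0.
    """
    if not points:
        raise ValueError("average_precision needs at least one PR point")
    pts = sorted(points, key=lambda p: p.recall)
    recalls = np.array([p.recall for p in pts])
    precisions = np.array([p.precision for p in pts])
    # envelope: running max of precision from the high-recall end
    envelope = np.maximum.accumulate(precisions[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recalls, envelope):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def mean_average_precision(aps: Mapping[ClassLabel, float]) -> float:
    """Arithmetic mean of per-class average precisions."""
    if not aps:
        raise ValueError("mean_average_precision needs at least one class")
    return float(sum(aps.values()) / len(aps))


@dataclass
class ClassReport:
    precision: float
    recall: float
    ap50: float
    ap50_95: float


def evaluate(
    preds: Sequence[Detection],
    gts: Sequence[GroundTruth],
    conf_threshold: float = 0.50,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> dict[ClassLabel, ClassReport]:
    """Per-class P, R (at the confidence threshold), AP@0.5 and AP@0.5:0.95.

    Only classes present in predictions or ground truth appear in the
    result; AP uses all predictions (the PR sweep), P/R only those above
    the confidence threshold.
    """
    labels = sorted(
        {d.label for d in preds} | {lbl for lbl, _ in gts}, key=lambda l: l.index
    )
    confident = [d for d in preds if d.confidence >= conf_threshold]
    report = {}
    for label in labels:
        c = match_detections(
            [d for d in confident if d.label == label],
            [(l, r) for l, r in gts if l == label],
            iou_threshold,
        )
        p, r, _, _ = precision_recall_f1(c)
        curve50 = pr_curve(preds, gts, label, iou_threshold=0.50)
        ap50 = average_precision(curve50) if curve50 else 0.0
        aps = []
        for thr in COCO_IOU_THRESHOLDS:
            curve = pr_curve(preds, gts, label, iou_threshold=thr)
            aps.append(average_precision(curve) if curve else 0.0)
        report[label] = ClassReport(p, r, ap50, float(np.mean(aps)))
    return report
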