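"""Heatmap-driven abnormality localization and its evaluation.

Relevance maps are turned into box detections (connected components of the
display-thresholded map), each carrying a confidence score defined as the
highest heatmap value inside the box weighted by the model's abnormal-class
probability.  Detections are scored against ground-truth boxes with IoU,
precision-recall curves, average precision (AP) at a fixed IoU threshold,
and mAP averaged over IoU thresholds (default: 10 values evenly spaced in
[0.1, 0.6]).

Boxes are 0-based and half-open: ``[x_min, x_max) x [y_min, y_max)`` in
pixel coordinates, so area arithmetic is exact.  The annotation-CSV
convention (x, y, width, height) converts as ``x_max = x + width``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.measure import label as _cc_label, regionprops as _regionprops

from .exceptions import InputError
from .saliency import RelevanceMap

__all__ = [
    "BoundingBox",
    "Detection",
    "GroundTruthRecord",
    "PRCurve",
    "default_iou_thresholds",
    "extract_boxes",
    "iou",
    "match_detections",
    "pr_curve",
    "average_precision",
    "mean_average_precision",
    "mean_image_iou",
]


@dataclass(frozen=True, order=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open on both axes."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise InputError(
                f"degenerate box ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @classmethod
    def from_xywh(cls, x: float, y: float, width: float, height: float) -> "BoundingBox":
        return cls(x, y, x + width, y + height)

    def to_xywh(self) -> tuple[float, float, float, float]:
        return self.x_min, self.y_min, self.x_max - self.x_min, self.y_max - self.y_min


@dataclass(frozen=True)
class Detection:
    """A predicted box with a non-negative confidence score."""

    image_id: str
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.confidence) or self.confidence < 0:
            raise InputError(f"confidence must be finite and >= 0, got {self.confidence}")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Annotated boxes for one image; empty for normal images."""

    image_id: str
    boxes: tuple[BoundingBox, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "boxes", tuple(self.boxes))


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall points swept from strictest to loosest confidence."""

    points: tuple[tuple[float, float], ...]
    iou_threshold: float


def default_iou_thresholds(n: int = 10, lo: float = 0.1, hi: float = 0.6) -> np.ndarray:
    """The mAP@[0.1 0.6] grid: ``n`` evenly spaced values, endpoints included."""
    return np.linspace(lo, hi, n)


def extract_boxes(
    rmap: RelevanceMap,
    classification_score: float,
    min_area: int = 0,
    image_id: str = "",
) -> list[Detection]:
    """Propose detections from a display-thresholded relevance map.

    8-connected components of nonzero pixels become tight half-open boxes;
    components smaller than ``min_area`` pixels are dropped.  Confidence =
    (max map value inside the box) x ``classification_score`` — the
    highest heatmap score weighted by the model's class probability.
    """
    mask = rmap.values > 0
    if not mask.any():
        return []
    labels = _cc_label(mask, connectivity=2)
    dets: list[Detection] = []
    for region in _regionprops(labels, intensity_image=rmap.values):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox  # half-open rows/cols
        box = BoundingBox(x_min=c0, y_min=r0, x_max=c1, y_max=r1)
        conf = float(region.intensity_max) * float(classification_score)
        dets.append(Detection(image_id=image_id, box=box, confidence=conf))
    dets.sort(key=lambda d: -d.confidence)
    return dets


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes: overlap area / union area."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def _group_by_image(items: Iterable, key=lambda x: x.image_id) -> dict:
    groups: dict[str, list] = {}
    for it in items:
        groups.setdefault(key(it), []).append(it)
    return groups


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthRecord],
    iou_threshold: float,
) -> tuple[list[bool], dict[str, list[bool]]]:
    """Greedy confidence-ordered TP/FP assignment.

    Per image, detections are processed in descending confidence; each is a
    true positive if its best-IoU *unmatched* ground-truth box reaches
    ``iou_threshold`` (that box is then consumed), else a false positive.
    Returns per-detection labels aligned with the confidence-descending
    global order, plus per-image matched flags for the GT boxes.
    """
    gt_by_image = {g.image_id: list(g.boxes) for g in gts}
    matched = {img: [False] * len(boxes) for img, boxes in gt_by_image.items()}
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    labels: list[bool] = []
    for i in order:
        det = dets[i]
        boxes = gt_by_image.get(det.image_id, [])
        best_j, best_iou = -1, 0.0
        for j, gt_box in enumerate(boxes):
            if matched[det.image_id][j]:
                continue
            val = iou(det.box, gt_box)
            if val > best_iou:
                best_j, best_iou = j, val
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[det.image_id][best_j] = True
            labels.append(True)
        else:
            labels.append(False)
    return labels, matched


def pr_curve(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthRecord],
    iou_threshold: float,
) -> PRCurve:
    """Precision-recall curve over the confidence-threshold sweep.

    One point per distinct confidence value, strictest first: precision =
    TP/(TP+FP) and recall = TP/(total GT boxes) among detections at or
    above that confidence.
    """
    n_gt = sum(len(g.boxes) for g in gts)
    if n_gt == 0:
        raise InputError("recall undefined: no ground-truth boxes")
    if len(dets) == 0:
        return PRCurve(points=(), iou_threshold=iou_threshold)
    labels, _ = match_detections(dets, gts, iou_threshold)
    confs = sorted((d.confidence for d in dets), reverse=True)
    points: list[tuple[float, float]] = []
    tp = fp = 0
    for rank, (conf, is_tp) in enumerate(zip(confs, labels)):
        tp += int(is_tp)
        fp += int(not is_tp)
        # group ties: only emit a point after the last detection at a confidence
        if rank + 1 < len(confs) and confs[rank + 1] == conf:
            continue
        points.append((tp / (tp + fp), tp / n_gt))
    return PRCurve(points=tuple(points), iou_threshold=iou_threshold)


def average_precision(curve: PRCurve) -> float:
    """All-point AP: the recall-increment weighted sum of precision.

    ``AP = sum_i (r_i - r_{i-1}) * p_i`` with ``r_0 = 0`` over the sweep,
    i.e. the average precision across all recall values actually attained.
    An empty curve (no detections) scores 0.
    """
    ap = 0.0
    prev_recall = 0.0
    for precision, recall in curve.points:
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def mean_average_precision(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthRecord],
    thresholds: Sequence[float] | None = None,
) -> float:
    """mAP: mean AP over a set of IoU thresholds (default mAP@[0.1 0.6])."""
    if thresholds is None:
        thresholds = default_iou_thresholds()
    thresholds = list(thresholds)
    if len(thresholds) == 0:
        raise InputError("need at least one IoU threshold")
    return float(
        np.mean([average_precision(pr_curve(dets, gts, t)) for t in thresholds])
    )


def mean_image_iou(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthRecord],
) -> float:
    """Mean per-image IoU between detections and ground truth.

    Within each image, GT boxes and detections are greedily paired in
    descending IoU order (each box and each detection used at most once);
    unpaired GT boxes contribute IoU 0.  The image score is the mean over
    its GT boxes, and the returned value is the mean over images.  Every
    image in ``gts`` must carry at least one GT box.
    """
    det_by_image = _group_by_image(dets)
    image_scores: list[float] = []
    for gt in gts:
        if len(gt.boxes) == 0:
            raise InputError(f"image {gt.image_id!r} has no ground-truth boxes")
        cand = det_by_image.get(gt.image_id, [])
        pairs = sorted(
            ((iou(gt_box, det.box), gi, di)
             for gi, gt_box in enumerate(gt.boxes)
             for di, det in enumerate(cand)),
            key=lambda t: -t[0],
        )
        used_gt: set[int] = set()
        used_det: set[int] = set()
        per_gt = [0.0] * len(gt.boxes)
        for val, gi, di in pairs:
            if val <= 0.0 or gi in used_gt or di in used_det:
                continue
            per_gt[gi] = val
            used_gt.add(gi)
            used_det.add(di)
        image_scores.append(float(np.mean(per_gt)))
    return float(np.mean(image_scores)) if image_scores else 0.0
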