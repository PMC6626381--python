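"""Detection evaluation: the Intersection-Ratio metric, TP/FP matching,
precision/recall/F1, and count-validation statistics.

Predicted boxes are fixed-size windows while ground truth is a tight box,
so Intersection over Union would penalise every correct detection; the
pipeline instead scores a prediction by the Intersection Ratio

    IR = overlap area / predicted-box area,

the fraction of the *predicted* box covered by ground truth (asymmetric:
a prediction lying entirely inside a ground-truth box has IR = 1).  A
prediction is a true positive iff its best IR over all ground-truth boxes
reaches the threshold (0.5 by default).

Matching is one-to-many: several positive predictions may cover one
ground-truth box and all count as true positives, because positivity is a
per-box rule and overlapping window-grid predictions are expected on large
panicles.  Recall is therefore defined as the fraction of ground-truth
boxes covered by at least one positive prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import Box, ValidationError

DEFAULT_IR_THRESHOLD = 0.5


@dataclass
class MatchResult:
    """Per-prediction IR values/positivity and per-ground-truth coverage."""

    ir: list[float]
    is_positive: list[bool]
    gt_covered: list[bool]
    ir_threshold: float = DEFAULT_IR_THRESHOLD


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    n_gt: int

    def as_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall,
                "f1": self.f1, "tp": self.tp, "fp": self.fp,
                "n_gt": self.n_gt}


def intersection_ratio(pred: Box, gt: Box) -> float:
    """Overlap area divided by the predicted box's area; in [0, 1]."""
    return pred.intersection_area(gt) / pred.area


def match_detections(preds: list[Box], gts: list[Box],
                     ir_threshold: float = DEFAULT_IR_THRESHOLD) -> MatchResult:
    """Score each prediction by its best IR over all ground-truth boxes and
    mark each ground-truth box covered iff some positive prediction has
    IR >= threshold against it specifically."""
    ir_best = []
    is_positive = []
    covered = [False] * len(gts)
    for pred in preds:
        pair_ir = [intersection_ratio(pred, gt) for gt in gts]
        best = max(pair_ir, default=0.0)
        pos = best >= ir_threshold
        ir_best.append(best)
        is_positive.append(pos)
        if pos:
            for j, v in enumerate(pair_ir):
                if v >= ir_threshold:
                    covered[j] = True
    return MatchResult(ir=ir_best, is_positive=is_positive,
                       gt_covered=covered, ir_threshold=ir_threshold)


def detection_metrics(match: MatchResult) -> DetectionMetrics:
    """Precision / recall / F1 from a match result.

    With no predictions, precision is reported as 0 with a warning;
    likewise recall when there is no ground truth.
    """
    tp = sum(match.is_positive)
    fp = len(match.is_positive) - tp
    n_gt = len(match.gt_covered)
    if tp + fp == 0:
        warnings.warn("no predictions: precision reported as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if n_gt == 0:
        warnings.warn("no ground-truth boxes: recall reported as 0",
                      stacklevel=2)
        recall = 0.0
    else:
        recall = sum(match.gt_covered) / n_gt
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return DetectionMetrics(precision=precision, recall=recall, f1=f1,
                            tp=tp, fp=fp, n_gt=n_gt)


def evaluate_detections(pred_sets, annotated_images,
                        ir_threshold: float = DEFAULT_IR_THRESHOLD
                        ) -> tuple[DetectionMetrics, dict[str, DetectionMetrics]]:
    """Pool detections against ground truth image by image.

    ``pred_sets`` is a list of DetectionSet; ``annotated_images`` a list of
    AnnotatedImage.  Returns pooled metrics plus a per-image breakdown.
    Detections referencing unknown image ids are an error.
    """
    gt_by_id = {img.image_id: img.gt_boxes for img in annotated_images}
    per_image: dict[str, DetectionMetrics] = {}
    tp = fp = n_gt = covered = 0
    seen = set()
    for det in pred_sets:
        if det.image_id not in gt_by_id:
            raise ValidationError(
                f"detections reference unknown image {det.image_id!r}")
        seen.add(det.image_id)
        m = match_detections(det.boxes, gt_by_id[det.image_id], ir_threshold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_image[det.image_id] = detection_metrics(m)
        tp += per_image[det.image_id].tp
        fp += per_image[det.image_id].fp
        n_gt += per_image[det.image_id].n_gt
        covered += sum(m.gt_covered)
    for image_id, gts in gt_by_id.items():
        if image_id not in seen:
            n_gt += len(gts)
    if tp + fp == 0:
        warnings.warn("no predictions: precision reported as 0", stacklevel=2)
    if n_gt == 0:
        warnings.warn("no ground-truth boxes: recall reported as 0",
                      stacklevel=2)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = covered / n_gt if n_gt else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    pooled = DetectionMetrics(precision=precision, recall=recall, f1=f1,
                              tp=tp, fp=fp, n_gt=n_gt)
    return pooled, per_image


def pearson_correlation(x, y) -> float:
    """Pearson correlation coefficient between two count series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(
            f"series must be 1-D and equal length, got {x.shape} vs {y.shape}")
    if len(x) < 2:
        raise ValidationError("need at least 2 observations")
    if np.ptp(x) == 0:
        raise ValidationError("series x is constant (zero variance)")
    if np.ptp(y) == 0:
        raise ValidationError("series y is constant (zero variance)")
    return float(stats.pearsonr(x, y).statistic)


def count_deltas(counts) -> np.ndarray:
    """First differences of an ordered count series (length n-1)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValidationError("need an ordered series of length >= 2")
    return np.diff(counts)
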