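"""Detection and pose performance metrics.

Detection is scored by IoU-matched confusion counts (TP/FP/FN) with
precision Pr = TP/(TP+FP), recall Re = TP/(TP+FN) and
F1 = 2*Pr*Re/(Pr+Re), the standard single-class object-detection metrics.
Pose is scored by the mean absolute angle error, per-keypoint spatial
error vectors in nanometres, their two-dimensional standard deviation
sqrt(var(dx)+var(dy)), and the tip flip rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import BoundingBox, KeypointPose, iou, px_to_nm
from .pose import canonicalize_tip_labels

__all__ = [
    "DetectionMetrics",
    "PoseMetrics",
    "MatchResult",
    "match_detections",
    "precision_recall_f1",
    "mean_angle_error",
    "spatial_errors",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionMetrics:
    """Confusion counts and derived scores for one-class detection.

    ``precision``/``recall`` are None when their denominator is zero
    (undefined, not zero).  When both are defined but zero, ``f1`` is
    reported as 0.0 with ``degenerate`` set.
    """

    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None
    degenerate: bool = False

    def rounded(self, ndigits: int = 2) -> "DetectionMetrics":
        """Presentation form: scores rounded, counts untouched."""
        rnd = lambda v: None if v is None else round(v, ndigits)
        return DetectionMetrics(
            tp=self.tp, fp=self.fp, fn=self.fn,
            precision=rnd(self.precision), recall=rnd(self.recall),
            f1=rnd(self.f1), degenerate=self.degenerate,
        )


@dataclass
class PoseMetrics:
    """Angle and spatial error summaries for keypoint pose estimation."""

    mean_angle_error: float
    per_point_error_vectors: dict[str, np.ndarray]  # (n, 2) arrays, nm
    per_point_2d_std: dict[str, float]  # sqrt(var(dx)+var(dy)), nm
    per_point_mean_radial_error: dict[str, float]  # mean |error vector|, nm
    flip_rate: float
    n_pairs: int = 0


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    #: (pred index, gt index, iou) for each true positive.
    matches: tuple[tuple[int, int, float], ...] = ()


def match_detections(
    pred: list[BoundingBox],
    gt: list[BoundingBox],
    iou_threshold: float = 0.3,
) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truth.

    Predictions are visited in order of descending confidence (ties broken
    by smaller cx, then smaller cy, for determinism); each claims the
    still-unmatched ground-truth box of highest IoU provided that IoU is
    at least ``iou_threshold`` (a true positive), otherwise it counts as a
    false positive.  Ground-truth boxes left unmatched are false negatives.
    """
    order = sorted(range(len(pred)), key=lambda i: (-pred[i].confidence, pred[i].cx, pred[i].cy))
    unmatched = set(range(len(gt)))
    matches: list[tuple[int, int, float]] = []
    fp = 0
    for i in order:
        best_j, best_iou = -1, 0.0
        for j in unmatched:
            v = iou(pred[i], gt[j])
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            unmatched.discard(best_j)
            matches.append((i, best_j, best_iou))
        else:
            fp += 1
    return MatchResult(tp=len(matches), fp=fp, fn=len(unmatched), matches=tuple(matches))


def precision_recall_f1(tp: int, fp: int, fn: int) -> DetectionMetrics:
    """Compute Pr, Re, F1 from confusion counts.

    Values are kept at full float precision; round only at presentation
    (:meth:`DetectionMetrics.rounded`).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn == 0:
        raise ValueError("all counts are zero; metrics undefined")
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    degenerate = False
    if precision is None or recall is None:
        f1 = None
    elif precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        degenerate = True
    return DetectionMetrics(
        tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
        f1=f1, degenerate=degenerate,
    )


def _paired(pred_poses: list[KeypointPose], gt_poses: list[KeypointPose]):
    gt_by_id = {p.particle_id: p for p in gt_poses}
    pairs = []
    for pred in pred_poses:
        gt = gt_by_id.get(pred.particle_id)
        if gt is not None:
            pairs.append((pred, gt))
    return pairs


def mean_angle_error(
    pred_poses: list[KeypointPose], gt_poses: list[KeypointPose]
) -> float:
    """Mean over particles of |angle(pred) - angle(gt)| in degrees.

    Pairs are formed by particle_id; particles must be complete on their
    angle-defining keypoints.  Devices with several angle definitions
    contribute one absolute difference per definition.  Tip labeling is
    irrelevant because the included angle is swap-invariant.
    """
    pairs = _paired(pred_poses, gt_poses)
    errors = []
    for pred, gt in pairs:
        for i in range(len(pred.schema.angle_defs)):
            errors.append(abs(pred.angle(i) - gt.angle(i)))
    if not errors:
        raise ValueError("no paired complete poses to compare")
    return float(np.mean(errors))


def spatial_errors(
    pred_poses: list[KeypointPose],
    gt_poses: list[KeypointPose],
    nm_per_px: float,
    canonicalize: bool = True,
) -> PoseMetrics:
    """Per-keypoint spatial error statistics in nanometres.

    For schemas with a single (tip, vertex, tip) angle the predicted tips
    are first canonicalized against the reference by minimal total tip
    distance; ``flip_rate`` is the fraction of pairs where the swap was
    chosen.  Error vectors are (pred - gt) * nm_per_px; the 2D standard
    deviation is sqrt(var(dx) + var(dy)) with population variance, and the
    mean radial error (mean Euclidean norm) is reported alongside.
    """
    if not (nm_per_px > 0):
        raise ValueError("nm_per_px calibration must be > 0")
    pairs = _paired(pred_poses, gt_poses)
    if not pairs:
        raise ValueError("no paired poses to compare")
    vectors: dict[str, list[tuple[float, float]]] = {}
    n_flipped = 0
    n_canon = 0
    angle_errors = []
    for pred, gt in pairs:
        schema = pred.schema
        if canonicalize and len(schema.angle_defs) == 1:
            pred, flipped = canonicalize_tip_labels(pred, gt)
            n_flipped += int(flipped)
            n_canon += 1
        for i in range(len(schema.angle_defs)):
            angle_errors.append(abs(pred.angle(i) - gt.angle(i)))
        for name in schema.keypoint_names:
            p, g = pred.get(name), gt.get(name)
            if p is None or g is None:
                continue
            vectors.setdefault(name, []).append(
                (px_to_nm(p.x - g.x, nm_per_px), px_to_nm(p.y - g.y, nm_per_px))
            )
    per_point = {k: np.asarray(v, dtype=float) for k, v in vectors.items()}
    per_point_std = {
        k: float(np.sqrt(np.var(v[:, 0]) + np.var(v[:, 1])))
        for k, v in per_point.items()
    }
    per_point_radial = {
        k: float(np.mean(np.hypot(v[:, 0], v[:, 1]))) for k, v in per_point.items()
    }
    return PoseMetrics(
        mean_angle_error=float(np.mean(angle_errors)),
        per_point_error_vectors=per_point,
        per_point_2d_std=per_point_std,
        per_point_mean_radial_error=per_point_radial,
        flip_rate=(n_flipped / n_canon) if n_canon else 0.0,
        n_pairs=len(pairs),
    )
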