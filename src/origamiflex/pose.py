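"""Stage 2: estimate named keypoints on cropped particle images.

Defines the pose backend contract (a learned heatmap regressor can be
plugged in) and a classical reference backend: threshold, keep the
largest component, skeletonize, locate the skeleton branch point, refine
the vertex by intersecting least-squares lines fitted to the two arm
branches, and place each tip at the far end of its branch projected onto
the fitted arm line.

Keypoint confidence is a documented monotone score in [0, 1]:
``exp(-rms / residual_scale_px)`` where rms is the perpendicular RMS
residual of the arm skeleton pixels about the fitted line (both arms
combined for the vertex).  A clean straight arm has sub-pixel residuals
and scores near 1; a bent, merged or noisy component scores low.  On
failure (no branch point, fewer than two arms, blank crop) the estimator
returns an all-missing pose — failure is a value, not an exception.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Protocol, runtime_checkable

import numpy as np
from skimage.filters import gaussian as gaussian_blur
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from ._skeleton import fit_line, intersect_lines, skeleton_path, split_path
from .detection import ParticleCrop
from .geometry import DeviceSchema, KeypointPose, Point2D

__all__ = [
    "PoseBackend",
    "PoseParams",
    "ClassicalPoseEstimator",
    "classical_pose",
    "filter_pose_confidence",
    "canonicalize_tip_labels",
    "map_pose_to_micrograph",
]

logger = logging.getLogger(__name__)


@runtime_checkable
class PoseBackend(Protocol):
    """Contract for keypoint estimators (classical or learned)."""

    name: str

    def estimate(self, image: np.ndarray, schema: DeviceSchema) -> KeypointPose:
        """Return a pose in crop coordinates with per-point confidences."""
        ...


@dataclass
class PoseParams:
    """Classical pose estimator parameters (crop-space pixels)."""

    blur_sigma: float = 1.0
    threshold: float | None = None  # None -> Otsu
    invert: bool = False
    # the skeleton bends smoothly through the vertex and curls inward at
    # the frayed tip, so pixels near both ends of an arm run are excluded
    # from its line fit; at the default crop scale an arm is ~125 px long
    vertex_exclusion_px: float = 32.0
    tip_exclusion_px: float = 16.0
    min_arm_px: int = 8  # minimum split-run length along the skeleton path
    min_arm_len_px: float = 30.0  # minimum accepted vertex-to-tip distance
    angle_gate: tuple[float, float] = (20.0, 160.0)  # outside: not two arms
    # scaled so a clean arm fit (rms ~ 1.5 px) scores ~ 0.94 and a bent or
    # contaminated fit (rms > ~ 2 px) falls below the 0.92 gate
    residual_scale_px: float = 25.0
    min_component_area: float = 50.0
    nucleosome_area_range: tuple[float, float] = (100.0, 3000.0)
    nucleosome_min_solidity: float = 0.8


def _failure(schema: DeviceSchema, particle_id: str) -> KeypointPose:
    return KeypointPose(particle_id=particle_id, schema=schema, points={})


def _segment_and_skeletonize(
    image: np.ndarray, params: PoseParams
) -> tuple[np.ndarray, np.ndarray] | None:
    """Binarize the crop; return (largest-component mask, full mask)."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        return None
    if params.invert:
        img = img.max() - img
    if img.max() - img.min() < 1e-12:
        return None
    smoothed = gaussian_blur(img, sigma=params.blur_sigma, preserve_range=True)
    thresh = params.threshold if params.threshold is not None else threshold_otsu(smoothed)
    mask = smoothed > thresh
    labels = cc_label(mask, connectivity=2)
    if labels.max() == 0:
        return None
    sizes = np.bincount(labels.ravel())[1:]
    main = int(np.argmax(sizes)) + 1
    if sizes[main - 1] < params.min_component_area:
        return None
    return labels == main, mask


def _arm_fit(run_pixels: np.ndarray, corner: np.ndarray, params: PoseParams):
    """Line fit to one arm's skeleton run, away from both bent ends."""
    d = np.linalg.norm(run_pixels - corner, axis=1)
    pts = run_pixels[d >= params.vertex_exclusion_px]
    if len(pts) >= params.min_arm_px and params.tip_exclusion_px > 0:
        end = run_pixels[int(np.argmax(d))]
        keep = pts[np.linalg.norm(pts - end, axis=1) >= params.tip_exclusion_px]
        if len(keep) >= params.min_arm_px:
            pts = keep
    if len(pts) < params.min_arm_px:
        pts = run_pixels
    return fit_line(pts)


def _hinge_points(main_mask: np.ndarray, params: PoseParams):
    """Vertex + two tips from the skeleton path; None when not hinge-like.

    The skeleton of a two-arm particle is a single bent path; the optimal
    two-run split of that path locates the bend, line fits away from the
    bend give the arm axes, and their intersection refines the vertex.
    The skeleton tracks the arm *centerlines*, so the fitted lines are
    shifted by half the estimated arm width toward the opposite arm and
    each tip is extended by the same amount, landing the keypoints on the
    inner-edge annotation convention (the vertex is annotated where the
    arms' inner edges meet).
    """
    path = skeleton_path(main_mask)
    split = split_path(path, 2, min_len=max(params.min_arm_px, 4))
    if split is None:
        return None
    corner = path[split.breaks[0]]
    fits = [_arm_fit(run, corner, params) for run in split.runs]
    vertex = intersect_lines(fits[0][0], fits[0][1], fits[1][0], fits[1][1])
    if vertex is None or np.linalg.norm(vertex - corner) > 4.0 * params.vertex_exclusion_px:
        vertex = corner  # unstable intersection: fall back to the bend pixel
    # outward unit direction and raw tip per arm (centerline coordinates)
    dirs, raw_tips = [], []
    for run, (mean, direction, _) in zip(split.runs, fits):
        dist = np.linalg.norm(run - vertex, axis=1)
        end = run[int(np.argmax(dist))]
        tip = mean + float((end - mean) @ direction) * direction
        d = tip - vertex
        norm = float(np.linalg.norm(d))
        if norm < params.min_arm_len_px:
            return None
        dirs.append(d / norm)
        raw_tips.append(tip)
    included = math.degrees(math.atan2(
        abs(dirs[0][0] * dirs[1][1] - dirs[0][1] * dirs[1][0]),
        float(dirs[0] @ dirs[1]),
    ))
    lo, hi = params.angle_gate
    if not (lo <= included <= hi):
        return None  # collinear rod or degenerate split, not a two-arm pose
    # centerline -> inner edge: shift each arm line half a width inward
    half_w = 0.5 * float(main_mask.sum()) / max(len(path), 1)
    half_w = min(max(half_w, 1.0), 20.0)
    shifted = []
    for i, (other, d) in enumerate(zip((dirs[1], dirs[0]), dirs)):
        n = np.array([-d[1], d[0]])
        if float(n @ other) < 0:
            n = -n  # inner side faces the other arm
        shifted.append((fits[i][0] + half_w * n, d, n))
    refined = intersect_lines(shifted[0][0], shifted[0][1],
                              shifted[1][0], shifted[1][1])
    if refined is not None:
        vertex = refined
    tips = [tip + half_w * n + half_w * d
            for tip, (_, d, n) in zip(raw_tips, shifted)]
    rms = [f[2] for f in fits]
    conf = [math.exp(-r / params.residual_scale_px) for r in rms]
    vertex_conf = math.exp(-(rms[0] + rms[1]) / (2.0 * params.residual_scale_px))
    return vertex, tips, conf, vertex_conf


def _pose_hinge(image: np.ndarray, schema: DeviceSchema, params: PoseParams,
                particle_id: str) -> KeypointPose:
    seg = _segment_and_skeletonize(image, params)
    if seg is None:
        return _failure(schema, particle_id)
    main_mask, full_mask = seg
    result = _hinge_points(main_mask, params)
    if result is None:
        return _failure(schema, particle_id)
    vertex, tips, tip_conf, vertex_conf = result
    points = {
        "tip_a": (Point2D(*tips[0]), tip_conf[0]),
        "vertex": (Point2D(*vertex), vertex_conf),
        "tip_b": (Point2D(*tips[1]), tip_conf[1]),
    }
    if "nucleosome" in schema.keypoint_names:
        nuc = _find_nucleosome(full_mask, main_mask, params)
        if nuc is not None:
            points["nucleosome"] = nuc
    return KeypointPose(particle_id=particle_id, schema=schema, points=points)


def _find_nucleosome(full_mask: np.ndarray, main_mask: np.ndarray,
                     params: PoseParams):
    """Most compact bright blob distinct from the device component."""
    other = full_mask & ~main_mask
    labels = cc_label(other, connectivity=2)
    lo, hi = params.nucleosome_area_range
    best = None
    for region in regionprops(labels):
        if not (lo <= region.area <= hi):
            continue
        if region.solidity < params.nucleosome_min_solidity:
            continue
        score = region.solidity * (1.0 - region.eccentricity * 0.5)
        if best is None or score > best[0]:
            cy, cx = region.centroid
            best = (score, Point2D(cx, cy), region.solidity)
    if best is None:
        return None
    return best[1], min(1.0, best[2])


def _pose_steridyn(image: np.ndarray, schema: DeviceSchema, params: PoseParams,
                   particle_id: str) -> KeypointPose:
    """Arm-base-arm: the skeleton path splits into three straight runs."""
    seg = _segment_and_skeletonize(image, params)
    if seg is None:
        return _failure(schema, particle_id)
    main_mask, _ = seg
    path = skeleton_path(main_mask)
    split = split_path(path, 3, min_len=max(params.min_arm_px, 4))
    if split is None:
        return _failure(schema, particle_id)
    corners = [path[i] for i in split.breaks]
    arm_runs = (split.runs[0], split.runs[2])
    base_fit = fit_line(split.runs[1])
    vertices, tips, confs = [], [], []
    for c_hint, run in zip(corners, arm_runs):
        mean, direction, rms = _arm_fit(run, c_hint, params)
        v = intersect_lines(mean, direction, base_fit[0], base_fit[1])
        if v is None or np.linalg.norm(v - c_hint) > 4.0 * params.vertex_exclusion_px:
            v = c_hint
        dist = np.linalg.norm(run - v, axis=1)
        end = run[int(np.argmax(dist))]
        tips.append(mean + float((end - mean) @ direction) * direction)
        vertices.append(v)
        confs.append(math.exp(-(rms + base_fit[2]) / (2.0 * params.residual_scale_px)))
    # label by position: "left" = smaller x (ties: smaller y)
    order = sorted(range(2), key=lambda i: (vertices[i][0], vertices[i][1]))
    li, ri = order[0], order[1]
    points = {
        "vertex_l": (Point2D(*vertices[li]), confs[li]),
        "tip_l": (Point2D(*tips[li]), confs[li]),
        "vertex_r": (Point2D(*vertices[ri]), confs[ri]),
        "tip_r": (Point2D(*tips[ri]), confs[ri]),
    }
    return KeypointPose(particle_id=particle_id, schema=schema, points=points)


def classical_pose(
    image: np.ndarray,
    schema: DeviceSchema,
    params: PoseParams | None = None,
    particle_id: str = "",
) -> KeypointPose:
    """Skeleton-based keypoint estimation on one particle crop.

    Dispatches on the schema: hinge and hinge-nucleosome use the
    single-branch-point two-arm model; SteriDyn uses the two-vertex
    base-plus-arms model.  Blank or unusable crops give an all-missing
    pose with zero confidence.
    """
    params = params or PoseParams()
    if schema.name in ("hinge", "hinge_nucleosome"):
        return _pose_hinge(image, schema, params, particle_id)
    if schema.name == "steridyn":
        return _pose_steridyn(image, schema, params, particle_id)
    raise ValueError(f"classical backend does not support schema {schema.name!r}")


@dataclass
class ClassicalPoseEstimator:
    """:class:`PoseBackend` wrapper around :func:`classical_pose`."""

    params: PoseParams | None = None
    name: str = "classical"

    def estimate(self, image: np.ndarray, schema: DeviceSchema) -> KeypointPose:
        return classical_pose(image, schema, self.params)


def filter_pose_confidence(
    poses: list[KeypointPose], threshold: float = 0.92
) -> list[KeypointPose]:
    """Keep poses whose angle-defining keypoints ALL meet the threshold.

    An angle computed from even one low-confidence point is untrustworthy,
    so gating is all-or-nothing over the angle-defining points; the
    number dropped is logged.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    kept = []
    for pose in poses:
        names = pose.schema.angle_point_names
        if pose.is_complete(names) and all(
            pose.confidence(n) >= threshold for n in names
        ):
            kept.append(pose)
    logger.info("pose confidence gate %.2f: %d in, %d kept, %d dropped",
                threshold, len(poses), len(kept), len(poses) - len(kept))
    return kept


def canonicalize_tip_labels(
    pred: KeypointPose, ref: KeypointPose
) -> tuple[KeypointPose, bool]:
    """Resolve the arbitrary tip-label ambiguity of a two-arm device.

    The two tips of a hinge are physically indistinguishable, so a
    predicted pose may carry its tip labels swapped relative to the
    reference.  Both assignments are evaluated and the one minimizing the
    total tip Euclidean distance is returned; ``flipped`` is True iff the
    swap was chosen (ties keep the original labels).  The vertex is never
    touched, and the included angle is invariant under the swap.
    """
    if len(pred.schema.angle_defs) != 1:
        raise ValueError("tip canonicalization applies to single-angle schemas")
    t1, _, t2 = pred.schema.angle_defs[0]
    for pose in (pred, ref):
        if pose.get(t1) is None or pose.get(t2) is None:
            raise ValueError(f"pose {pose.particle_id!r} is missing a tip")
    d_same = (pred.get(t1).distance_to(ref.get(t1))
              + pred.get(t2).distance_to(ref.get(t2)))
    d_swap = (pred.get(t1).distance_to(ref.get(t2))
              + pred.get(t2).distance_to(ref.get(t1)))
    if d_swap < d_same:
        points = dict(pred.points)
        points[t1], points[t2] = points[t2], points[t1]
        return replace(pred, points=points), True
    return pred, False


def map_pose_to_micrograph(pose: KeypointPose, crop: ParticleCrop) -> KeypointPose:
    """Map a crop-space pose into micrograph coordinates.

    Uses the crop's recorded affine window; for square (unclipped) crops
    this is a similarity transform and included angles are preserved
    exactly.  Raises ValueError when provenance is missing.
    """
    if crop is None:
        raise ValueError("crop provenance is required to map a pose back")
    points = {
        name: (crop.to_micrograph(pt), conf)
        for name, (pt, conf) in pose.points.items()
    }
    return replace(pose, points=points)
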