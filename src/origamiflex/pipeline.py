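"""End-to-end pipeline: detect -> filter -> crop -> pose -> mechanics.

Mirrors the two-stage characterization workflow: stage 1 proposes
bounding boxes and filters them (confidence threshold, non-maximum
suppression, aspect-ratio/size filter), stage 2 estimates keypoints on
the cropped particles and gates them by confidence, and the surviving
angle ensemble is converted into a probability distribution, a
Boltzmann-inverted free-energy landscape and a torque profile.  When
ground truth is available (synthetic data) the detection and pose
metrics are computed alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, derive_seed
from .detection import (
    ParticleCrop,
    bbf_filter,
    classical_detect,
    crop_particles,
    filter_by_confidence,
    nms,
)
from .evaluation import (
    DetectionMetrics,
    PoseMetrics,
    match_detections,
    mean_angle_error,
    precision_recall_f1,
    spatial_errors,
)
from .geometry import BoundingBox, KeypointPose, Micrograph, get_schema
from .io import read_micrograph, write_keypoint_csv, write_yolo_labels
from .mechanics import (
    AngleDistribution,
    FreeEnergyLandscape,
    angles_to_distribution,
    boltzmann_invert,
    ks_two_sample,
    torque_from_energy,
)
from .pose import classical_pose, filter_pose_confidence, map_pose_to_micrograph
from .simulate import generate_micrograph, sample_angles

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "StageCounts", "run_pipeline"]


@dataclass
class StageCounts:
    """Per-stage box/pose bookkeeping; each filter conserves counts."""

    proposed: int = 0
    after_confidence: int = 0
    after_nms: int = 0
    after_bbf: int = 0
    cropped: int = 0
    posed: int = 0
    after_pose_gate: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PipelineResult:
    angles: np.ndarray
    distribution: AngleDistribution | None
    landscape: FreeEnergyLandscape | None
    torque: np.ndarray | None
    counts: StageCounts
    detection_metrics: DetectionMetrics | None = None
    pose_metrics: PoseMetrics | None = None
    ks_statistic: float | None = None
    ks_p_value: float | None = None
    n_images: int = 0
    summary: dict = field(default_factory=dict)


def _process_image(
    micrograph: Micrograph, config: RunConfig, image_name: str, counts: StageCounts
) -> tuple[list[BoundingBox], list[KeypointPose]]:
    """Detection + pose for one micrograph; returns final boxes and
    micrograph-space poses (pre confidence gate)."""
    schema = get_schema(config.schema)
    proposals = classical_detect(micrograph, config.detection)
    confident = filter_by_confidence(proposals, config.conf_threshold)
    suppressed = nms(confident, config.iou_threshold)
    final_boxes = bbf_filter(suppressed, config.bbf_max_aspect, config.bbf_square_size)
    counts.proposed += len(proposals)
    counts.after_confidence += len(confident)
    counts.after_nms += len(suppressed)
    counts.after_bbf += len(final_boxes)
    # conservation: every filter only removes
    assert len(confident) <= len(proposals)
    assert len(suppressed) <= len(confident)
    assert len(final_boxes) <= len(suppressed)
    crops = crop_particles(micrograph, final_boxes, config.crop_size)
    counts.cropped += len(crops)
    poses = []
    for crop in crops:
        pid = f"{image_name}_{crop.particle_id}"
        pose = classical_pose(crop.image, schema, config.pose, particle_id=pid)
        pose = map_pose_to_micrograph(pose, crop)
        pose.image = image_name
        poses.append(pose)
    counts.posed += len(poses)
    return final_boxes, poses


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Run the full pipeline per the run configuration.

    Synthetic mode (default): generates ``config.n_images`` micrographs
    with ground truth and evaluates detection/pose metrics plus a
    two-sample KS test of the recovered angles against a fresh sample
    from the generating law.  When ``config.images_dir`` is set, PNGs in
    that directory are processed instead and no metrics are computed.
    Deterministic for a fixed configuration.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "labels").mkdir(parents=True, exist_ok=True)
    counts = StageCounts()
    all_poses: list[KeypointPose] = []
    gt_boxes_per_image: list[tuple[list[BoundingBox], list[BoundingBox]]] = []
    gt_poses: list[KeypointPose] = []
    gt_angles: list[float] = []
    n_images = 0

    if config.images_dir is not None:
        image_paths = sorted(Path(config.images_dir).glob("*.png"))
        sources = [(p.stem, read_micrograph(p, config.nm_per_px), None) for p in image_paths]
    else:
        rng = np.random.default_rng(derive_seed(config.seed, "simulate"))
        image_seeds = rng.integers(0, 2**31 - 1, size=config.n_images)
        sources = []
        for i in range(config.n_images):
            sim = config.simulation
            sim = type(sim).from_dict({**sim.to_dict(), "seed": int(image_seeds[i])})
            micrograph, records = generate_micrograph(sim)
            sources.append((f"img_{i:04d}", micrograph, records))

    match_pairs: list[tuple[KeypointPose, KeypointPose]] = []
    tp = fp = fn = 0
    for image_name, micrograph, records in sources:
        n_images += 1
        boxes, poses = _process_image(micrograph, config, image_name, counts)
        all_poses.extend(poses)
        if out is not None:
            write_yolo_labels(boxes, out / "labels" / f"{image_name}.txt",
                              (micrograph.width, micrograph.height))
        if records is not None:
            targets = [r for r in records if r.particle_class == "target_hinge"]
            gt_boxes = [r.true_box for r in targets]
            result = match_detections(boxes, gt_boxes, config.iou_threshold)
            tp += result.tp
            fp += result.fp
            fn += result.fn
            for pred_idx, gt_idx, _ in result.matches:
                gt_pose = targets[gt_idx].true_pose
                match_pairs.append((poses[pred_idx], gt_pose))
            gt_poses.extend(t.true_pose for t in targets)
            for t in targets:
                gt_angles.extend(t.true_angles)

    gated = filter_pose_confidence(all_poses, config.pose_conf_threshold)
    counts.after_pose_gate = len(gated)
    angles = np.array([a for pose in gated for a in pose.angles()])

    distribution = landscape = torque = None
    if angles.size:
        distribution = angles_to_distribution(angles, config.bin_width)
        landscape = boltzmann_invert(distribution, pseudocount=config.pseudocount)
        try:
            torque = torque_from_energy(landscape)
        except ValueError:
            torque = None

    detection_metrics = pose_metrics = None
    ks_stat = ks_p = None
    if gt_angles:
        detection_metrics = precision_recall_f1(tp, fp, fn)
        # pose metrics over confidence-gated matched pairs, paired by id
        gated_ids = {p.particle_id for p in gated}
        pred_matched = [p for p, _ in match_pairs if p.particle_id in gated_ids]
        gt_matched = [
            KeypointPose(particle_id=p.particle_id, schema=g.schema,
                         points=dict(g.points), image=g.image)
            for p, g in match_pairs if p.particle_id in gated_ids
        ]
        if pred_matched:
            pose_metrics = spatial_errors(pred_matched, gt_matched, config.nm_per_px)
        if angles.size:
            reference = sample_angles(
                config.simulation.angle_law, max(len(gt_angles), angles.size),
                derive_seed(config.seed, "ks-reference"),
            )
            ks_stat, ks_p = ks_two_sample(angles, reference)

    summary = {
        "n_images": n_images,
        "counts": counts.as_dict(),
        "n_angles": int(angles.size),
        "bin_width_deg": config.bin_width,
        "detection": None if detection_metrics is None else {
            "tp": detection_metrics.tp, "fp": detection_metrics.fp,
            "fn": detection_metrics.fn,
            "precision": detection_metrics.precision,
            "recall": detection_metrics.recall,
            "f1": detection_metrics.f1,
        },
        "pose": None if pose_metrics is None else {
            "mean_angle_error_deg": pose_metrics.mean_angle_error,
            "flip_rate": pose_metrics.flip_rate,
            "per_point_2d_std_nm": pose_metrics.per_point_2d_std,
            "n_pairs": pose_metrics.n_pairs,
        },
        "ks": None if ks_stat is None else {"D": ks_stat, "p_value": ks_p},
    }

    if out is not None:
        if gated:
            write_keypoint_csv(gated, out / "keypoints.csv")
        if angles.size:
            pd.DataFrame({"angle_deg": angles}).to_csv(out / "angles.csv", index=False)
        if landscape is not None:
            frame = pd.DataFrame({
                "bin_center_deg": landscape.bin_centers,
                "probability": distribution.probabilities,
                "energy_kT": landscape.energy,
                "torque_kT_per_deg": torque if torque is not None else np.nan,
            })
            frame.to_csv(out / "landscape.csv", index=False, float_format="%.6f")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)

    return PipelineResult(
        angles=angles,
        distribution=distribution,
        landscape=landscape,
        torque=torque,
        counts=counts,
        detection_metrics=detection_metrics,
        pose_metrics=pose_metrics,
        ks_statistic=ks_stat,
        ks_p_value=ks_p,
        n_images=n_images,
        summary=summary,
    )
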