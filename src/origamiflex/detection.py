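"""Stage 1: find isolated target particles in micrographs.

The module defines the detector backend contract (any callable object
mapping a micrograph to confidence-scored bounding boxes — a trained
network can be plugged in here) and ships a classical reference backend
built on thresholding, morphology and connected components, so the whole
pipeline runs without any trained weights.

Classical confidence score: each connected component is scored by the
geometric mean of (a) an area score, a Gaussian falloff of the relative
deviation of the component area from the expected two-arm area, and (b) a
two-arm shape score: the fraction of component pixels lying within a half
arm-width of the best two-segment (vertex + two arms) fit to the
component skeleton, times a bend score that decays to zero as the two
fitted segments become collinear (an edge-on hinge projects as a straight
rod and is not an analyzable particle).  Both factors are in [0, 1] and
decrease monotonically with area mismatch and shape mismatch.

Box convention: components that pass a two-arm shape test are proposed as
*square* boxes (side = the larger tight extent), mirroring the square
annotation convention the real detector is trained to reproduce;
malformed components (rods, boundary fragments, blobs) keep their tight
extents, which is what lets the aspect-ratio filter (BBF) remove them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian as gaussian_blur
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, disk, opening
from skimage.transform import resize

from ._skeleton import intersect_lines, segment_coverage, skeleton_path, split_path
from .geometry import BoundingBox, Micrograph, Point2D, iou

__all__ = [
    "DetectorBackend",
    "DetectionParams",
    "ClassicalDetector",
    "classical_detect",
    "nms",
    "bbf_filter",
    "filter_by_confidence",
    "crop_particles",
    "ParticleCrop",
]

logger = logging.getLogger(__name__)


@runtime_checkable
class DetectorBackend(Protocol):
    """Contract for particle detectors (classical or learned)."""

    name: str

    def detect(self, micrograph: Micrograph) -> list[BoundingBox]:
        """Return confidence-scored boxes within image bounds."""
        ...


@dataclass
class DetectionParams:
    """Classical detector parameters.

    Defaults are calibrated to the simulator's default geometry (70 nm /
    50 px arms, ~10 nm / 7 px width at 1.4 nm/px); recalibrate via
    :meth:`from_simulation` when the geometry changes.
    """

    blur_sigma: float = 2.0
    threshold: float | None = None  # None -> Otsu
    # Otsu always splits something; require real foreground/background
    # separation so a particle-free image yields no detections
    min_contrast: float = 0.1
    open_radius: int = 1
    close_radius: int = 2
    min_area: float = 250.0
    max_area: float = 4500.0
    expected_area: float = 1100.0  # measured two-arm component area, px^2
    area_tolerance: float = 0.6  # relative deviation for area-score falloff
    shape_halfwidth_px: float = 7.0
    min_arm_px: float = 15.0
    two_arm_angle_range: tuple[float, float] = (25.0, 155.0)
    bend_scale_deg: float = 30.0  # bend-score falloff: straight rods -> ~0
    square_proposals: bool = True
    invert: bool = False

    @classmethod
    def from_simulation(cls, sim_config) -> "DetectionParams":
        """Derive geometry-dependent parameters from a SimulationConfig."""
        arm_l = sim_config.arm_length_px
        # blur + thresholding widen each arm by roughly one blur sigma per side
        eff_w = sim_config.arm_width_px + 2.0 * sim_config.edge_blur_px
        expected = 2.0 * arm_l * eff_w
        return cls(
            min_area=0.25 * expected,
            max_area=4.0 * expected,
            expected_area=expected,
            shape_halfwidth_px=eff_w / 2.0 + 2.0,
            min_arm_px=0.3 * arm_l,
        )


def _component_score(
    mask: np.ndarray, area: float, params: DetectionParams
) -> tuple[float, bool]:
    """Confidence in [0, 1] and a two-arm verdict for one component mask."""
    rel = (area - params.expected_area) / (params.area_tolerance * params.expected_area)
    area_score = math.exp(-rel * rel)

    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    two_arm = False
    bend_score = 0.2  # fallback for components too small to split
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    path = skeleton_path(mask)
    split = split_path(path, 2, min_len=8) if len(path) >= 16 else None
    if split is not None:
        vertex = intersect_lines(*split.lines[0], *split.lines[1])
        corner = path[split.breaks[0]]
        if vertex is None or np.linalg.norm(vertex - corner) > 10.0:
            vertex = corner
        tips = [split.runs[0][0], split.runs[1][-1]]
        segments = [(vertex, tip) for tip in tips]
        lens = [float(np.linalg.norm(tip - vertex)) for tip in tips]
        v1, v2 = tips[0] - vertex, tips[1] - vertex
        dot = float(v1 @ v2)
        cross = float(v1[0] * v2[1] - v1[1] * v2[0])
        angle = math.degrees(math.atan2(abs(cross), dot))
        # a straight rod splits into two near-collinear runs (bend ~ 0);
        # a genuine two-arm particle is visibly bent at the vertex
        bend = 180.0 - angle
        bend_score = 1.0 - math.exp(-((bend / params.bend_scale_deg) ** 2))
        lo, hi = params.two_arm_angle_range
        two_arm = min(lens) >= params.min_arm_px and lo <= angle <= hi
    elif len(path) >= 2:
        segments = [(path[0], path[-1])]
    else:
        segments = [(pts[0], pts[-1])]
    shape_score = segment_coverage(pts, segments, params.shape_halfwidth_px) * bend_score
    confidence = min(1.0, math.sqrt(max(area_score, 0.0) * max(shape_score, 0.0)))
    return confidence, two_arm


def classical_detect(
    m: Micrograph, params: DetectionParams | None = None
) -> list[BoundingBox]:
    """Reference detector: threshold -> morphology -> components -> score.

    Returns boxes sorted by descending confidence.  A blank or
    background-only image yields an empty list, not an error.
    """
    params = params or DetectionParams()
    img = m.pixels.astype(float)
    if params.invert:
        img = img.max() - img
    smoothed = gaussian_blur(img, sigma=params.blur_sigma, preserve_range=True)
    if params.threshold is not None:
        thresh = params.threshold
    else:
        if smoothed.max() - smoothed.min() < 1e-12:
            return []
        thresh = threshold_otsu(smoothed)
    mask = smoothed > thresh
    if params.threshold is None and mask.any() and (not mask.all()):
        contrast = smoothed[mask].mean() - smoothed[~mask].mean()
        if contrast < params.min_contrast:
            return []  # particle-free image: Otsu split noise, not structure
    if params.open_radius > 0:
        mask = opening(mask, disk(params.open_radius))
    if params.close_radius > 0:
        mask = closing(mask, disk(params.close_radius))
    labels = cc_label(mask, connectivity=2)
    boxes: list[BoundingBox] = []
    for region in regionprops(labels):
        area = float(region.area)
        if area < params.min_area or area > params.max_area:
            continue
        confidence, two_arm = _component_score(region.image, area, params)
        minr, minc, maxr, maxc = region.bbox
        w, h = float(maxc - minc), float(maxr - minr)
        cx, cy = (minc + maxc) / 2.0, (minr + maxr) / 2.0
        # border-touching components are partial particles: keep the tight
        # extent (as a detector trained on whole particles would hug the
        # visible sliver) so the aspect filter can remove them downstream
        at_border = (minr <= 1 or minc <= 1
                     or maxr >= m.height - 1 or maxc >= m.width - 1)
        if two_arm and not at_border and params.square_proposals:
            side = max(w, h)
            w = h = side
        box = BoundingBox(cx=cx, cy=cy, w=w, h=h, confidence=confidence)
        clipped = box.clipped_to(m.width, m.height)
        if clipped is not None:
            boxes.append(clipped)
    boxes.sort(key=lambda b: (-b.confidence, b.cx, b.cy))
    return boxes


@dataclass
class ClassicalDetector:
    """:class:`DetectorBackend` wrapper around :func:`classical_detect`."""

    params: DetectionParams | None = None
    name: str = "classical"

    def detect(self, micrograph: Micrograph) -> list[BoundingBox]:
        return classical_detect(micrograph, self.params)


def nms(boxes: list[BoundingBox], iou_threshold: float) -> list[BoundingBox]:
    """Greedy non-maximum suppression.

    Repeatedly keep the highest-confidence box and discard remaining
    boxes overlapping a kept box with IoU above the threshold.  Ties are
    broken by (confidence, then smaller cx, then smaller cy).
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold must be in [0, 1], got {iou_threshold}")
    pending = sorted(boxes, key=lambda b: (-b.confidence, b.cx, b.cy))
    kept: list[BoundingBox] = []
    for box in pending:
        if all(iou(box, other) <= iou_threshold for other in kept):
            kept.append(box)
    return kept


def bbf_filter(
    boxes: list[BoundingBox],
    max_aspect: float = 1.5,
    square_size: float = 50.0,
) -> list[BoundingBox]:
    """Bounding-box-size filter (BBF).

    Removes boxes with aspect ratio (max/min side) above ``max_aspect``
    and re-defines every survivor as a ``square_size`` x ``square_size``
    square at its original center, mirroring the square annotation
    convention.  Order and confidences are preserved.
    """
    if not (square_size > 0):
        raise ValueError(f"square_size must be > 0, got {square_size}")
    out = []
    for box in boxes:
        if box.aspect_ratio > max_aspect:
            continue
        out.append(box.resized(square_size, square_size))
    logger.info("BBF: %d boxes in, %d kept, %d removed",
                len(boxes), len(out), len(boxes) - len(out))
    return out


def filter_by_confidence(
    boxes: list[BoundingBox], threshold: float = 0.47
) -> list[BoundingBox]:
    """Keep boxes with confidence >= threshold (inclusive), order preserved."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return [b for b in boxes if b.confidence >= threshold]


@dataclass
class ParticleCrop:
    """A cropped particle image plus the affine map back to the micrograph.

    The crop resamples the (clipped) box region to ``out_size`` squared;
    the map is a similarity transform (angle-preserving) exactly when the
    clipped region is square, which is the case for every unclipped
    post-BBF box.
    """

    image: np.ndarray
    box: BoundingBox
    x0: int
    y0: int
    x1: int
    y1: int
    out_size: int
    particle_id: str = ""

    @property
    def scale_x(self) -> float:
        return (self.x1 - self.x0) / self.out_size

    @property
    def scale_y(self) -> float:
        return (self.y1 - self.y0) / self.out_size

    def to_micrograph(self, p: Point2D) -> Point2D:
        return Point2D(self.x0 + p.x * self.scale_x, self.y0 + p.y * self.scale_y)

    def to_crop(self, p: Point2D) -> Point2D:
        return Point2D((p.x - self.x0) / self.scale_x, (p.y - self.y0) / self.scale_y)

    def provenance(self) -> dict:
        return {
            "particle_id": self.particle_id,
            "x0": self.x0, "y0": self.y0, "x1": self.x1, "y1": self.y1,
            "out_size": self.out_size,
            "box": {"cx": self.box.cx, "cy": self.box.cy, "w": self.box.w,
                    "h": self.box.h, "confidence": self.box.confidence},
        }


def crop_particles(
    m: Micrograph, boxes: list[BoundingBox], out_size: int = 200
) -> list[ParticleCrop]:
    """Crop each box region from the micrograph, resampled to a square.

    Boxes are clipped to the image first; a box whose clipped region has
    zero area is skipped with a logged warning.  Each crop records the
    integer source window so crop-space keypoints map back to micrograph
    coordinates exactly.
    """
    crops: list[ParticleCrop] = []
    for k, box in enumerate(boxes):
        x0 = max(int(math.floor(box.x_min)), 0)
        y0 = max(int(math.floor(box.y_min)), 0)
        x1 = min(int(math.ceil(box.x_max)), m.width)
        y1 = min(int(math.ceil(box.y_max)), m.height)
        if x1 <= x0 or y1 <= y0:
            logger.warning("skipping zero-area clipped box %d at (%.1f, %.1f)",
                           k, box.cx, box.cy)
            continue
        sub = m.pixels[y0:y1, x0:x1]
        image = resize(sub, (out_size, out_size), order=1,
                       preserve_range=True, anti_aliasing=False)
        crops.append(ParticleCrop(
            image=image, box=box, x0=x0, y0=y0, x1=x1, y1=y1,
            out_size=out_size, particle_id=f"d{k:03d}",
        ))
    return crops
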