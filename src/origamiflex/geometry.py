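"""Shared geometric and domain primitives.

Coordinate convention used everywhere in this package: continuous, 0-based,
origin at the top-left of the image, x increasing rightward, y increasing
downward (image convention).  Boxes are axis-aligned real rectangles stored
as center + size, matching the on-disk YOLO convention after
denormalization; no pixel quantization is applied in overlap computations.
Angles are reported in degrees; internal trigonometry is in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Point2D",
    "BoundingBox",
    "Micrograph",
    "DeviceSchema",
    "KeypointPose",
    "angle_at_vertex",
    "iou",
    "px_to_nm",
    "HINGE",
    "HINGE_NUCLEOSOME",
    "STERIDYN",
    "get_schema",
]


@dataclass(frozen=True)
class Point2D:
    """A 2D point in pixel units (top-left origin, y-down)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates: ({self.x}, {self.y})")

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class BoundingBox:
    """A candidate particle location: center + size + detection confidence."""

    cx: float
    cy: float
    w: float
    h: float
    confidence: float = 1.0
    class_id: int = 0

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.cx, self.cy, self.w, self.h)):
            raise ValueError("non-finite box parameters")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box size must be positive, got w={self.w}, h={self.h}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def x_min(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def x_max(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def y_min(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def y_max(self) -> float:
        return self.cy + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def aspect_ratio(self) -> float:
        """max(w, h) / min(w, h); always >= 1."""
        return max(self.w, self.h) / min(self.w, self.h)

    def resized(self, w: float, h: float) -> "BoundingBox":
        """Same center, confidence and class, new size."""
        return replace(self, w=w, h=h)

    def contains_point(self, p: Point2D, tol: float = 0.0) -> bool:
        return (
            self.x_min - tol <= p.x <= self.x_max + tol
            and self.y_min - tol <= p.y <= self.y_max + tol
        )

    def clipped_to(self, width: float, height: float) -> "BoundingBox | None":
        """Intersection with the image rectangle [0, width] x [0, height].

        Returns None when the clipped region has zero area.
        """
        x0 = max(self.x_min, 0.0)
        y0 = max(self.y_min, 0.0)
        x1 = min(self.x_max, float(width))
        y1 = min(self.y_max, float(height))
        if x1 <= x0 or y1 <= y0:
            return None
        return replace(
            self, cx=(x0 + x1) / 2.0, cy=(y0 + y1) / 2.0, w=x1 - x0, h=y1 - y0
        )


@dataclass
class Micrograph:
    """A grayscale micrograph with its pixel-size calibration.

    ``pixels`` is a 2D float array; intensities are nominally in [0, 1]
    (bright particles on dark background for negative stain, unless a
    pipeline inverts polarity upstream).  ``nm_per_px`` calibrates spatial
    measurements; the default 1.4 nm/px at the working 960-px scale maps a
    50 px arm to the nominal 70 nm hinge-arm length.
    """

    pixels: np.ndarray
    nm_per_px: float = 1.4

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected 2D grayscale array, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("micrograph intensities must be finite")
        if not (self.nm_per_px > 0):
            raise ValueError(f"nm_per_px must be > 0, got {self.nm_per_px}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class DeviceSchema:
    """Declares a device's named keypoints and which triples define angles.

    ``angle_defs`` entries are (tip, vertex, tip) triples: the angle is the
    included angle at the middle (vertex) point.  ``position_points`` are
    keypoints tracked as positions only (e.g. a bound nucleosome).
    """

    name: str
    keypoint_names: tuple[str, ...]
    angle_defs: tuple[tuple[str, str, str], ...]
    position_points: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.keypoint_names)) != len(self.keypoint_names):
            raise ValueError("keypoint names must be unique")
        known = set(self.keypoint_names)
        for triple in self.angle_defs:
            if len(triple) != 3:
                raise ValueError(f"angle definition must be a triple, got {triple}")
            for name in triple:
                if name not in known:
                    raise ValueError(f"angle point {name!r} not among keypoints")
        for name in self.position_points:
            if name not in known:
                raise ValueError(f"position point {name!r} not among keypoints")

    @property
    def angle_point_names(self) -> tuple[str, ...]:
        """Keypoints participating in at least one angle, in schema order."""
        used = {n for triple in self.angle_defs for n in triple}
        return tuple(n for n in self.keypoint_names if n in used)


#: Two stiff arms joined at a flexible vertex; one included angle.
HINGE = DeviceSchema(
    name="hinge",
    keypoint_names=("tip_a", "vertex", "tip_b"),
    angle_defs=(("tip_a", "vertex", "tip_b"),),
)

#: Hinge plus a nucleosome tracked as a position-only point.
HINGE_NUCLEOSOME = DeviceSchema(
    name="hinge_nucleosome",
    keypoint_names=("tip_a", "vertex", "tip_b", "nucleosome"),
    angle_defs=(("tip_a", "vertex", "tip_b"),),
    position_points=("nucleosome",),
)

#: Two fluctuating arms on a base platform; each arm angle is measured at
#: its own vertex against the segment to the opposite vertex (the base).
STERIDYN = DeviceSchema(
    name="steridyn",
    keypoint_names=("tip_l", "vertex_l", "vertex_r", "tip_r"),
    angle_defs=(
        ("tip_l", "vertex_l", "vertex_r"),
        ("tip_r", "vertex_r", "vertex_l"),
    ),
)

_SCHEMAS = {s.name: s for s in (HINGE, HINGE_NUCLEOSOME, STERIDYN)}


def get_schema(name: str) -> DeviceSchema:
    """Look up a built-in device schema by name."""
    try:
        return _SCHEMAS[name]
    except KeyError:
        raise KeyError(
            f"unknown schema {name!r}; known: {sorted(_SCHEMAS)}"
        ) from None


@dataclass
class KeypointPose:
    """Named keypoints with per-point confidences for one particle.

    ``points`` maps keypoint name -> (Point2D, confidence).  A keypoint
    absent from the map is *missing* (e.g. the estimator failed on it);
    an all-missing pose is the documented failure value of estimators.
    """

    particle_id: str
    schema: DeviceSchema
    points: dict[str, tuple[Point2D, float]] = field(default_factory=dict)
    image: str = ""

    def __post_init__(self) -> None:
        known = set(self.schema.keypoint_names)
        for name, (pt, conf) in self.points.items():
            if name not in known:
                raise ValueError(
                    f"point {name!r} not in schema {self.schema.name!r}"
                )
            if not (0.0 <= conf <= 1.0):
                raise ValueError(f"confidence for {name!r} must be in [0,1], got {conf}")

    def get(self, name: str) -> Point2D | None:
        entry = self.points.get(name)
        return entry[0] if entry is not None else None

    def confidence(self, name: str) -> float:
        entry = self.points.get(name)
        return entry[1] if entry is not None else 0.0

    @property
    def missing_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.schema.keypoint_names if n not in self.points)

    def is_complete(self, names: Iterable[str] | None = None) -> bool:
        names = self.schema.keypoint_names if names is None else tuple(names)
        return all(n in self.points for n in names)

    def angle(self, which: int = 0) -> float:
        """Included angle (degrees) for the given angle definition."""
        t1, v, t2 = self.schema.angle_defs[which]
        pts = [self.get(n) for n in (t1, v, t2)]
        if any(p is None for p in pts):
            raise ValueError(
                f"pose {self.particle_id!r} incomplete for angle {which}"
            )
        return angle_at_vertex(pts[0], pts[1], pts[2])

    def angles(self) -> tuple[float, ...]:
        return tuple(self.angle(i) for i in range(len(self.schema.angle_defs)))


def angle_at_vertex(tip1: Point2D, vertex: Point2D, tip2: Point2D) -> float:
    """Included angle at ``vertex`` between vertex->tip1 and vertex->tip2.

    Returns degrees in [0, 180].  Invariant under swapping the tips and
    under any rigid rotation/translation/uniform scaling of all three
    points.  Raises ValueError when a tip coincides with the vertex (the
    angle is undefined).
    """
    ax, ay = tip1.x - vertex.x, tip1.y - vertex.y
    bx, by = tip2.x - vertex.x, tip2.y - vertex.y
    if (ax == 0.0 and ay == 0.0) or (bx == 0.0 and by == 0.0):
        raise ValueError("degenerate input: a tip coincides with the vertex")
    dot = ax * bx + ay * by
    cross = ax * by - ay * bx
    return math.degrees(math.atan2(abs(cross), dot))


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes as continuous real rectangles."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def px_to_nm(value: float, nm_per_px: float) -> float:
    """Convert a pixel measurement to nanometres."""
    if not (nm_per_px > 0):
        raise ValueError(f"nm_per_px must be > 0, got {nm_per_px}")
    return value * nm_per_px
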