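"""Synthetic negative-stain TEM micrograph generator with known ground truth.

Emulates the feature classes seen in real hinge micrographs: isolated
two-arm hinges (the analysis targets), vertically-oriented hinges that
project as single rods (no visible second arm), local aggregates of two
or three touching hinges, free blobs, and hinges cut by the image border,
all over a background of base level + low-frequency mottle (stain
variation) + pixel noise.  Particles
are rendered bright on a dark background, matching the negative-stain
convention where structures appear light against the stain; set
``invert=True`` in the configuration for the opposite polarity.

Ground truth follows the annotation rule used for real data: the vertex
is the intersection of the two arms' *inner* edges and each tip is the
inner-edge endpoint, so the included angle recomputed from the ground
truth keypoints equals the sampled angle exactly.

The generator is the package's study-condition definition: its defaults
(960-px images, ~70 nm arms at 1.4 nm/px, ~20 target hinges per image,
truncated-Gaussian angle law centered at 90 degrees) are fixed, and every
random choice flows from the configuration seed, so identical
configurations produce byte-identical images.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .geometry import (
    HINGE,
    BoundingBox,
    DeviceSchema,
    KeypointPose,
    Micrograph,
    Point2D,
    angle_at_vertex,
    get_schema,
)

__all__ = [
    "AngleLaw",
    "SimulationConfig",
    "GroundTruthRecord",
    "sample_angles",
    "render_hinge",
    "generate_micrograph",
    "generate_dataset",
]


@dataclass(frozen=True)
class AngleLaw:
    """A distribution over hinge angles in degrees, supported on [0, 180].

    Families: ``uniform(low, high)``, ``gaussian(mean, sd)`` (resampled
    into [0, 180]; indistinguishable from truncation when the tails are
    negligible, as for the default parameters), ``truncated-gaussian``
    with explicit bounds, and ``empirical-histogram`` (uniform within
    bins).
    """

    family: str
    params: tuple[tuple[str, float | tuple[float, ...]], ...]

    @classmethod
    def uniform(cls, low: float = 0.0, high: float = 180.0) -> "AngleLaw":
        if not (0.0 <= low <= high <= 180.0):
            raise ValueError(f"uniform bounds must satisfy 0 <= {low} <= {high} <= 180")
        return cls("uniform", (("low", low), ("high", high)))

    @classmethod
    def gaussian(cls, mean: float, sd: float) -> "AngleLaw":
        if not (0.0 <= mean <= 180.0) or sd < 0:
            raise ValueError(f"need mean in [0,180] and sd >= 0, got {mean}, {sd}")
        return cls("gaussian", (("mean", mean), ("sd", sd)))

    @classmethod
    def truncated_gaussian(
        cls, mean: float, sd: float, low: float = 0.0, high: float = 180.0
    ) -> "AngleLaw":
        if not (0.0 <= low < high <= 180.0):
            raise ValueError(f"truncation bounds must satisfy 0 <= {low} < {high} <= 180")
        if sd < 0:
            raise ValueError(f"sd must be >= 0, got {sd}")
        return cls(
            "truncated-gaussian",
            (("mean", mean), ("sd", sd), ("low", low), ("high", high)),
        )

    @classmethod
    def empirical(cls, bin_edges, probabilities) -> "AngleLaw":
        edges = tuple(float(e) for e in bin_edges)
        probs = tuple(float(p) for p in probabilities)
        if len(probs) != len(edges) - 1:
            raise ValueError("need len(probabilities) == len(bin_edges) - 1")
        if edges[0] < 0 or edges[-1] > 180 or any(
            b <= a for a, b in zip(edges, edges[1:])
        ):
            raise ValueError("bin edges must be increasing and within [0, 180]")
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        return cls(
            "empirical-histogram", (("bin_edges", edges), ("probabilities", probs))
        )

    def _p(self, key: str):
        return dict(self.params)[key]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. angles in degrees; all within [0, 180]."""
        if n < 0:
            raise ValueError(f"n must be >= 0, got {n}")
        if n == 0:
            return np.empty(0, dtype=float)
        if self.family == "uniform":
            return rng.uniform(self._p("low"), self._p("high"), size=n)
        if self.family in ("gaussian", "truncated-gaussian"):
            mean, sd = self._p("mean"), self._p("sd")
            low, high = (0.0, 180.0)
            if self.family == "truncated-gaussian":
                low, high = self._p("low"), self._p("high")
            if sd == 0.0:
                if not (low <= mean <= high):
                    raise ValueError("degenerate law mean outside truncation bounds")
                return np.full(n, mean, dtype=float)
            out = np.empty(n, dtype=float)
            filled = 0
            while filled < n:  # rejection into the support
                draw = rng.normal(mean, sd, size=n - filled)
                keep = draw[(draw >= low) & (draw <= high)]
                out[filled : filled + keep.size] = keep
                filled += keep.size
            return out
        if self.family == "empirical-histogram":
            edges = np.asarray(self._p("bin_edges"))
            probs = np.asarray(self._p("probabilities"))
            idx = rng.choice(len(probs), size=n, p=probs)
            return rng.uniform(edges[idx], edges[idx + 1])
        raise ValueError(f"unknown angle-law family {self.family!r}")

    def to_dict(self) -> dict:
        return {"family": self.family, "params": {k: v for k, v in self.params}}

    @classmethod
    def from_dict(cls, d: dict) -> "AngleLaw":
        family, params = d["family"], d["params"]
        if family == "uniform":
            return cls.uniform(params["low"], params["high"])
        if family == "gaussian":
            return cls.gaussian(params["mean"], params["sd"])
        if family == "truncated-gaussian":
            return cls.truncated_gaussian(
                params["mean"], params["sd"], params["low"], params["high"]
            )
        if family == "empirical-histogram":
            return cls.empirical(params["bin_edges"], params["probabilities"])
        raise ValueError(f"unknown angle-law family {family!r}")


def sample_angles(angle_law: AngleLaw, n: int, seed) -> np.ndarray:
    """Sample ``n`` angles from ``angle_law``, reproducibly under ``seed``.

    ``seed`` may be an integer or an already-constructed Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return angle_law.sample(n, rng)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic micrograph (or a dataset of them).

    Geometry defaults mirror the real system: 960-px working scale,
    70 nm (~50 px) stiff arms of ~10 nm width meeting at a flexible
    vertex, about 20 analyzable hinges per image plus distractors.
    """

    image_size: int = 960
    nm_per_px: float = 1.4
    arm_length_nm: float = 70.0
    arm_width_nm: float = 10.0
    angle_law: AngleLaw = field(
        default_factory=lambda: AngleLaw.truncated_gaussian(90.0, 15.0)
    )
    n_target_hinges: int = 20
    n_vertical_distractors: int = 4
    n_aggregates: int = 3
    n_free_blobs: int = 6
    n_boundary_fragments: int = 3
    particle_intensity: float = 0.45
    background_level: float = 0.25
    noise_sd: float = 0.05
    mottle_scale: float = 120.0
    mottle_sd: float = 0.03
    edge_blur_px: float = 1.2
    tip_taper: float = 0.15  # chamfer fraction at arm far ends (fraying)
    device: str = "hinge"
    nucleosome_radius_nm: float = 5.5
    base_length_nm: float = 70.0
    invert: bool = False
    seed: int = 0
    max_place_attempts: int = 1000
    placement_gap_px: float = 10.0

    def __post_init__(self) -> None:
        counts = (
            self.n_target_hinges,
            self.n_vertical_distractors,
            self.n_aggregates,
            self.n_free_blobs,
            self.n_boundary_fragments,
        )
        if any(c < 0 for c in counts):
            raise ValueError("particle counts must be >= 0")
        if self.image_size <= 0:
            raise ValueError("image_size must be > 0")
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px must be > 0")
        if self.device not in ("hinge", "hinge_nucleosome", "steridyn"):
            raise ValueError(f"unknown device {self.device!r}")

    @property
    def arm_length_px(self) -> float:
        return self.arm_length_nm / self.nm_per_px

    @property
    def arm_width_px(self) -> float:
        return self.arm_width_nm / self.nm_per_px

    @property
    def schema(self) -> DeviceSchema:
        return get_schema(self.device)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["angle_law"] = self.angle_law.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        law = d.get("angle_law")
        if isinstance(law, dict):
            d["angle_law"] = AngleLaw.from_dict(law)
        return cls(**d)


@dataclass
class GroundTruthRecord:
    """Ground truth for one rendered scene element.

    ``true_pose``/``true_angles`` are populated for target devices only;
    distractor classes (vertical rod, aggregate, blob) are detection
    negatives with no meaningful pose.
    """

    particle_id: str
    #: target_hinge | vertical_distractor | aggregate | blob | boundary_fragment
    particle_class: str
    true_box: BoundingBox
    true_pose: KeypointPose | None = None
    true_angles: tuple[float, ...] = ()

    @property
    def true_angle(self) -> float | None:
        return self.true_angles[0] if self.true_angles else None


def _unit(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a)])


def _arm_polygon(vertex: np.ndarray, direction: np.ndarray, normal: np.ndarray,
                 length: float, width: float, taper: float = 0.0) -> np.ndarray:
    """Arm polygon with inner edge vertex -> vertex + length*direction and
    width extending along ``normal`` (the outward side).

    ``taper`` chamfers the outer corner of the far end by that fraction
    of the length, emulating the frayed helix ends of real arms: the
    inner-edge tip stays exact while the visible tip shape softens.
    """
    v0 = vertex
    v1 = vertex + length * direction
    pullback = min(taper, 0.9) * length * direction
    return np.array([v0, v1, v1 - pullback + width * normal, v0 + width * normal])


def _hinge_polygons(angle: float, rotation: float, length: float, width: float,
                    taper: float = 0.0):
    """Arm polygons and keypoints for a hinge with vertex at the origin.

    ``rotation`` orients the bisector of the included angle.  Keypoints
    follow the inner-edge annotation rule: vertex at the inner-edge
    intersection (the origin), tips at the inner-edge endpoints.
    """
    bis = _unit(rotation)
    d1, d2 = _unit(rotation - angle / 2.0), _unit(rotation + angle / 2.0)
    polys = []
    for d in (d1, d2):
        n = np.array([-d[1], d[0]])
        if float(n @ bis) > 0:  # outward = away from the bisector
            n = -n
        polys.append(_arm_polygon(np.zeros(2), d, n, length, width, taper))
    keypoints = {
        "vertex": np.zeros(2),
        "tip_a": length * d1,
        "tip_b": length * d2,
    }
    return polys, keypoints


def _steridyn_polygons(angles: tuple[float, float], rotation: float,
                       length: float, base_length: float, width: float,
                       taper: float = 0.0):
    """Base platform from vertex_l to vertex_r plus one arm per vertex.

    Each arm angle is the included angle at its vertex between its tip and
    the opposite vertex; both arms extend on the same side of the base.
    """
    b = _unit(rotation)
    n_base = np.array([-b[1], b[0]])  # arms on the -n side, base body on +n
    vl = np.zeros(2)
    vr = base_length * b
    d_l = _unit(rotation + angles[0])
    d_r = _unit(rotation + 180.0 - angles[1])
    if float(d_l @ n_base) > 0:  # force both arms to the -n side
        d_l = _unit(rotation - angles[0])
        d_r = _unit(rotation + 180.0 + angles[1])
    polys = [_arm_polygon(vl, b, n_base, base_length, width)]  # base
    for vertex, d, other in ((vl, d_l, vr), (vr, d_r, vl)):
        n_arm = np.array([-d[1], d[0]])
        if float(n_arm @ (other - vertex)) > 0:
            n_arm = -n_arm  # width extends away from the device interior
        polys.append(_arm_polygon(vertex, d, n_arm, length, width, taper))
    keypoints = {
        "vertex_l": vl,
        "vertex_r": vr,
        "tip_l": vl + length * d_l,
        "tip_r": vr + length * d_r,
    }
    return polys, keypoints


def _paint_polygons(layer: np.ndarray, polys, intensity: float, blur: float) -> None:
    """Rasterize polygons with soft edges into ``layer`` (max-composited)."""
    pts = np.vstack(polys)
    pad = int(math.ceil(3 * blur)) + 2
    x0 = int(math.floor(pts[:, 0].min())) - pad
    y0 = int(math.floor(pts[:, 1].min())) - pad
    x1 = int(math.ceil(pts[:, 0].max())) + pad
    y1 = int(math.ceil(pts[:, 1].max())) + pad
    h, w = layer.shape
    x0c, y0c, x1c, y1c = max(x0, 0), max(y0, 0), min(x1, w), min(y1, h)
    if x1c <= x0c or y1c <= y0c:
        return
    patch = np.zeros((y1 - y0, x1 - x0))
    for poly in polys:
        rr, cc = draw_polygon(poly[:, 1] - y0, poly[:, 0] - x0, shape=patch.shape)
        patch[rr, cc] = intensity
    if blur > 0:
        patch = gaussian_filter(patch, blur)
    region = layer[y0c:y1c, x0c:x1c]
    np.maximum(region, patch[y0c - y0 : y1c - y0, x0c - x0 : x1c - x0], out=region)


def _paint_disk(layer: np.ndarray, center: np.ndarray, radius: float,
                intensity: float, blur: float) -> None:
    pad = int(math.ceil(radius + 3 * blur)) + 2
    x0, y0 = int(math.floor(center[0])) - pad, int(math.floor(center[1])) - pad
    size = 2 * pad + 1
    patch = np.zeros((size, size))
    rr, cc = draw_disk((center[1] - y0, center[0] - x0), radius, shape=patch.shape)
    patch[rr, cc] = intensity
    if blur > 0:
        patch = gaussian_filter(patch, blur)
    h, w = layer.shape
    x0c, y0c = max(x0, 0), max(y0, 0)
    x1c, y1c = min(x0 + size, w), min(y0 + size, h)
    if x1c <= x0c or y1c <= y0c:
        return
    region = layer[y0c:y1c, x0c:x1c]
    np.maximum(region, patch[y0c - y0 : y1c - y0, x0c - x0 : x1c - x0], out=region)


def _square_box(pts: np.ndarray, margin: float) -> BoundingBox:
    """Smallest square (plus margin) covering the points, as a BoundingBox."""
    x0, y0 = pts[:, 0].min() - margin, pts[:, 1].min() - margin
    x1, y1 = pts[:, 0].max() + margin, pts[:, 1].max() + margin
    side = max(x1 - x0, y1 - y0)
    return BoundingBox(cx=(x0 + x1) / 2.0, cy=(y0 + y1) / 2.0, w=side, h=side)


def _tight_box(pts: np.ndarray, margin: float) -> BoundingBox:
    x0, y0 = pts[:, 0].min() - margin, pts[:, 1].min() - margin
    x1, y1 = pts[:, 0].max() + margin, pts[:, 1].max() + margin
    return BoundingBox(cx=(x0 + x1) / 2.0, cy=(y0 + y1) / 2.0, w=x1 - x0, h=y1 - y0)


def _build_target(config: SimulationConfig, angles: tuple[float, ...],
                  rotation: float, center: np.ndarray,
                  nucleosome_offset: tuple[float, float] | None = None):
    """Polygons + ground truth for one target device centered at ``center``.

    ``center`` is the center of the particle's bounding box, so that
    placement collision checks operate on the realized box.
    """
    L, W = config.arm_length_px, config.arm_width_px
    if config.device == "steridyn":
        polys, kps = _steridyn_polygons(
            (angles[0], angles[1]), rotation, L,
            config.base_length_nm / config.nm_per_px, W, config.tip_taper,
        )
    else:
        polys, kps = _hinge_polygons(angles[0], rotation, L, W, config.tip_taper)
    pts = np.vstack(polys)
    shift = center - (pts.min(axis=0) + pts.max(axis=0)) / 2.0
    polys = [p + shift for p in polys]
    kps = {k: v + shift for k, v in kps.items()}
    disk_center = None
    if config.device == "hinge_nucleosome":
        # nucleosome sits in the hinge opening, along the bisector
        radial, lateral = nucleosome_offset if nucleosome_offset else (0.45, 0.0)
        bis = _unit(rotation)
        disk_center = kps["vertex"] + (radial * L) * bis + lateral * np.array([-bis[1], bis[0]])
        kps["nucleosome"] = disk_center
    margin = 2.0 * config.edge_blur_px + 1.0
    all_pts = np.vstack([np.vstack(polys)] + (
        [disk_center + np.array([[-1, -1], [1, 1]]) * config.nucleosome_radius_nm / config.nm_per_px]
        if disk_center is not None else []
    ))
    box = _square_box(all_pts, margin)
    return polys, kps, disk_center, box


def render_hinge(
    canvas: Micrograph,
    angle: float,
    global_rotation: float,
    center: Point2D,
    config: SimulationConfig,
    particle_id: str = "p000",
) -> GroundTruthRecord:
    """Draw one two-arm hinge onto ``canvas`` and return its ground truth.

    ``center`` is the bounding-box center of the rendered particle and
    must sit at least one arm length inside the canvas.  Raises
    ValueError when the particle would exceed the canvas.
    """
    L = config.arm_length_px
    if not (L <= center.x <= canvas.width - L and L <= center.y <= canvas.height - L):
        raise ValueError("center must be at least one arm length inside the canvas")
    polys, kps, _, box = _build_target(
        replace(config, device="hinge"), (angle,), global_rotation,
        np.array([center.x, center.y]),
    )
    if (box.x_min < 0 or box.y_min < 0 or box.x_max > canvas.width
            or box.y_max > canvas.height):
        raise ValueError("particle would exceed the canvas")
    layer = np.zeros_like(canvas.pixels)
    _paint_polygons(layer, polys, config.particle_intensity, config.edge_blur_px)
    canvas.pixels += layer
    pose = KeypointPose(
        particle_id=particle_id,
        schema=HINGE,
        points={k: (Point2D(*v), 1.0) for k, v in kps.items()},
    )
    return GroundTruthRecord(
        particle_id=particle_id,
        particle_class="target_hinge",
        true_box=box,
        true_pose=pose,
        true_angles=(angle,),
    )


def _boxes_collide(box: BoundingBox, others: list[BoundingBox], gap: float) -> bool:
    for other in others:
        if (box.x_min - gap < other.x_max and box.x_max + gap > other.x_min
                and box.y_min - gap < other.y_max and box.y_max + gap > other.y_min):
            return True
    return False


def generate_micrograph(
    config: SimulationConfig,
) -> tuple[Micrograph, list[GroundTruthRecord]]:
    """Render one micrograph with complete ground truth.

    Target devices are placed without overlap (rejection sampling with a
    bounded retry count); vertical rods, aggregates and blobs are placed
    clear of everything already on the canvas.  Deterministic under the
    configuration seed.  Raises RuntimeError naming the achieved count
    when a requested count cannot be placed.
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    L = config.arm_length_px
    layer = np.zeros((size, size))
    records: list[GroundTruthRecord] = []
    placed: list[BoundingBox] = []
    schema = config.schema
    n_angles = len(schema.angle_defs)
    counter = 0

    def _next_id() -> str:
        nonlocal counter
        pid = f"p{counter:03d}"
        counter += 1
        return pid

    def _place(build_box, margin: float, what: str, index: int, total: int):
        for _ in range(config.max_place_attempts):
            center = rng.uniform(margin, size - margin, size=2)
            candidate = build_box(center)
            if not _boxes_collide(candidate, placed, config.placement_gap_px):
                return center, candidate
        raise RuntimeError(
            f"could not place {what} {index + 1} of {total} "
            f"after {config.max_place_attempts} attempts ({index} placed)"
        )

    # --- target devices -------------------------------------------------
    target_angles = config.angle_law.sample(config.n_target_hinges * n_angles, rng)
    for i in range(config.n_target_hinges):
        angles = tuple(target_angles[i * n_angles : (i + 1) * n_angles])
        rotation = rng.uniform(0.0, 360.0)
        nuc_offset = (rng.uniform(0.30, 0.60), rng.uniform(-0.1, 0.1) * L) \
            if config.device == "hinge_nucleosome" else None

        def build(center, angles=angles, rotation=rotation, nuc=nuc_offset):
            return _build_target(config, angles, rotation, center, nuc)[3]

        margin = L * 1.6 + config.placement_gap_px
        center, _ = _place(build, margin, "target device", i, config.n_target_hinges)
        polys, kps, disk_center, box = _build_target(config, angles, rotation, center, nuc_offset)
        _paint_polygons(layer, polys, config.particle_intensity, config.edge_blur_px)
        if disk_center is not None:
            _paint_disk(layer, disk_center,
                        config.nucleosome_radius_nm / config.nm_per_px,
                        config.particle_intensity, config.edge_blur_px)
        pid = _next_id()
        pose = KeypointPose(
            particle_id=pid, schema=schema,
            points={k: (Point2D(*v), 1.0) for k, v in kps.items()},
        )
        placed.append(box)
        records.append(GroundTruthRecord(
            particle_id=pid, particle_class="target_hinge", true_box=box,
            true_pose=pose, true_angles=angles,
        ))

    # --- aggregates: 2-3 mutually overlapping hinges --------------------
    for i in range(config.n_aggregates):
        n_members = int(rng.integers(2, 4))
        member_angles = config.angle_law.sample(n_members, rng)
        rotations = rng.uniform(0.0, 360.0, size=n_members)
        offsets = rng.uniform(-0.4 * L, 0.4 * L, size=(n_members, 2))
        offsets[0] = 0.0

        def build(center, angs=member_angles, rots=rotations, offs=offsets):
            pts = []
            for a, r, off in zip(angs, rots, offs):
                polys, _ = _hinge_polygons(a, r, L, config.arm_width_px, config.tip_taper)
                pts.append(np.vstack(polys) + off)
            pts = np.vstack(pts)
            mid = (pts.min(axis=0) + pts.max(axis=0)) / 2.0
            return _square_box(pts - mid + center, 2.0 * config.edge_blur_px + 1.0)

        margin = L * 2.2 + config.placement_gap_px
        center, box = _place(build, margin, "aggregate", i, config.n_aggregates)
        pts_all = []
        for a, r, off in zip(member_angles, rotations, offsets):
            polys, _ = _hinge_polygons(a, r, L, config.arm_width_px, config.tip_taper)
            pts_all.append([np.vstack(polys) + off])
        flat = np.vstack([np.vstack(group[0]) for group in pts_all])
        mid = (flat.min(axis=0) + flat.max(axis=0)) / 2.0
        for a, r, off in zip(member_angles, rotations, offsets):
            polys, _ = _hinge_polygons(a, r, L, config.arm_width_px, config.tip_taper)
            polys = [p + off - mid + center for p in polys]
            _paint_polygons(layer, polys, config.particle_intensity, config.edge_blur_px)
        placed.append(box)
        records.append(GroundTruthRecord(
            particle_id=_next_id(), particle_class="aggregate", true_box=box,
        ))

    # --- vertical distractors: single rods (hinge seen edge-on) ---------
    for i in range(config.n_vertical_distractors):
        rotation = rng.uniform(0.0, 360.0)

        def build(center, rotation=rotation):
            d = _unit(rotation)
            n = np.array([-d[1], d[0]])
            poly = _arm_polygon(center - d * L / 2.0 - n * config.arm_width_px / 2.0,
                                d, n, L, config.arm_width_px)
            return _tight_box(poly, 2.0 * config.edge_blur_px + 1.0)

        margin = L * 0.8 + 5.0
        center, box = _place(build, margin, "vertical distractor", i,
                             config.n_vertical_distractors)
        d = _unit(rotation)
        n = np.array([-d[1], d[0]])
        poly = _arm_polygon(center - d * L / 2.0 - n * config.arm_width_px / 2.0,
                            d, n, L, config.arm_width_px)
        _paint_polygons(layer, [poly], config.particle_intensity, config.edge_blur_px)
        placed.append(box)
        records.append(GroundTruthRecord(
            particle_id=_next_id(), particle_class="vertical_distractor", true_box=box,
        ))

    # --- boundary fragments: hinges cut by the image edge ----------------
    # The vertex sits just inside a border so part of the particle is
    # clipped away — the source of the elongated boundary detections that
    # the aspect-ratio filter (BBF) exists to remove.
    for i in range(config.n_boundary_fragments):
        angle = float(config.angle_law.sample(1, rng)[0])
        edge = int(rng.integers(0, 4))
        # bisector points out of frame (+/- 120 deg): the particle's bulk
        # is clipped away, leaving a bent sliver hugging the border
        inward = {0: 90.0, 1: 270.0, 2: 0.0, 3: 180.0}[edge]
        rotation = inward + 180.0 + rng.uniform(-120.0, 120.0)
        depth = rng.uniform(6.0, 0.3 * L)

        def build(center, angle=angle, rotation=rotation):
            polys, _ = _hinge_polygons(angle, rotation, L, config.arm_width_px, config.tip_taper)
            pts = np.vstack(polys) + center
            box = _tight_box(pts, 2.0 * config.edge_blur_px + 1.0)
            return box.clipped_to(size, size) or box

        # vertex pinned near the chosen border, free along it
        for _ in range(config.max_place_attempts):
            along = rng.uniform(L, size - L)
            if edge == 0:
                vertex_xy = np.array([along, depth])
            elif edge == 1:
                vertex_xy = np.array([along, size - depth])
            elif edge == 2:
                vertex_xy = np.array([depth, along])
            else:
                vertex_xy = np.array([size - depth, along])
            candidate = build(vertex_xy)
            if not _boxes_collide(candidate, placed, config.placement_gap_px):
                break
        else:
            raise RuntimeError(
                f"could not place boundary fragment {i + 1} of "
                f"{config.n_boundary_fragments} after {config.max_place_attempts} "
                f"attempts ({i} placed)"
            )
        polys, _ = _hinge_polygons(angle, rotation, L, config.arm_width_px, config.tip_taper)
        polys = [p + vertex_xy for p in polys]
        _paint_polygons(layer, polys, config.particle_intensity, config.edge_blur_px)
        placed.append(build(vertex_xy))
        records.append(GroundTruthRecord(
            particle_id=_next_id(), particle_class="boundary_fragment",
            true_box=build(vertex_xy),
        ))

    # --- free blobs ------------------------------------------------------
    for i in range(config.n_free_blobs):
        radius = rng.uniform(2.5, 5.0)

        def build(center, radius=radius):
            r = radius + 2.0 * config.edge_blur_px + 1.0
            return BoundingBox(cx=center[0], cy=center[1], w=2 * r, h=2 * r)

        center, box = _place(build, radius + 8.0, "blob", i, config.n_free_blobs)
        _paint_disk(layer, center, radius, config.particle_intensity,
                    config.edge_blur_px)
        placed.append(box)
        records.append(GroundTruthRecord(
            particle_id=_next_id(), particle_class="blob", true_box=box,
        ))

    # --- background: base + low-frequency mottle + pixel noise ----------
    image = np.full((size, size), config.background_level)
    if config.mottle_sd > 0:
        field_noise = rng.normal(0.0, 1.0, size=(size, size))
        mottle = gaussian_filter(field_noise, config.mottle_scale / 4.0)
        sd = mottle.std()
        if sd > 0:
            image += mottle * (config.mottle_sd / sd)
    image += layer
    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, size=(size, size))
    np.clip(image, 0.0, 1.0, out=image)
    if config.invert:
        image = 1.0 - image
    return Micrograph(pixels=image, nm_per_px=config.nm_per_px), records


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(pixels * 255.0), 0, 255).astype(np.uint8)


def generate_dataset(
    config: SimulationConfig, n_images: int, out_dir
) -> dict:
    """Write a dataset of micrographs with labels and a JSON manifest.

    Per image: a PNG, a YOLO-format label file (target devices only —
    distractor classes are unlabeled background, as in real annotation),
    and rows in a shared ground-truth keypoint CSV.  Per-image seeds are
    drawn deterministically from the master seed and recorded in the
    manifest.
    """
    from .io import write_keypoint_csv, write_yolo_labels  # avoid cycle at import

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    image_seeds = rng.integers(0, 2**31 - 1, size=n_images)
    entries = []
    poses: list[KeypointPose] = []
    all_angles: list[float] = []
    for i in range(n_images):
        name = f"img_{i:04d}"
        img_config = replace(config, seed=int(image_seeds[i]))
        micrograph, records = generate_micrograph(img_config)
        Image.fromarray(_to_uint8(micrograph.pixels), mode="L").save(
            out_dir / f"{name}.png"
        )
        targets = [r for r in records if r.particle_class == "target_hinge"]
        write_yolo_labels(
            [r.true_box for r in targets], out_dir / f"{name}.txt",
            config.image_size, include_confidence=False,
        )
        for r in targets:
            pose = r.true_pose
            pose.image = name
            poses.append(pose)
            all_angles.extend(r.true_angles)
        entries.append({
            "image": f"{name}.png",
            "labels": f"{name}.txt",
            "seed": int(image_seeds[i]),
            "n_targets": len(targets),
            "n_records": len(records),
        })
    if poses:
        write_keypoint_csv(poses, out_dir / "ground_truth_keypoints.csv")
    manifest = {
        "seed": config.seed,
        "n_images": n_images,
        "angle_law": config.angle_law.to_dict(),
        "config": config.to_dict(),
        "images": entries,
        "keypoints": "ground_truth_keypoints.csv" if poses else None,
        "true_angles": all_angles,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
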