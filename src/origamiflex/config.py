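"""Run configuration for the end-to-end pipeline.

One master seed drives every stage; per-stage generators are derived by
stable hashing of the stage name so adding a stage never perturbs the
randomness of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .detection import DetectionParams
from .pose import PoseParams
from .simulate import SimulationConfig

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed derived from the master seed; stable across runs and
    always below 2**31."""
    return int((master_seed ^ zlib.crc32(stage.encode())) % (2**31 - 1))


@dataclass
class RunConfig:
    """Everything needed to run simulate -> detect -> pose -> mechanics."""

    seed: int = 0
    nm_per_px: float = 1.4
    schema: str = "hinge"
    n_images: int = 20
    images_dir: str | None = None  # when set, load real images instead of simulating
    simulation: SimulationConfig = field(
        default_factory=SimulationConfig)
    detection: DetectionParams = field(
        default_factory=lambda: DetectionParams.from_simulation(SimulationConfig()))
    pose: PoseParams = field(default_factory=PoseParams)
    conf_threshold: float = 0.47
    iou_threshold: float = 0.3
    bbf_max_aspect: float = 1.5
    # annotation box side for the re-squaring step; matched to the
    # synthetic geometry (an enclosing square of a 50 px-arm hinge),
    # just as the 50 px side matched the real data's annotation boxes
    bbf_square_size: float = 80.0
    crop_size: int = 200
    pose_conf_threshold: float = 0.92
    bin_width: float = 5.0
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        # keep nested configs consistent with the top-level knobs
        self.simulation.nm_per_px = self.nm_per_px
        self.simulation.device = self.schema
        self.simulation.seed = derive_seed(self.seed, "simulate")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("simulation"), dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if isinstance(d.get("detection"), dict):
            det = d["detection"]
            if "two_arm_angle_range" in det:
                det["two_arm_angle_range"] = tuple(det["two_arm_angle_range"])
            d["detection"] = DetectionParams(**det)
        if isinstance(d.get("pose"), dict):
            pose = d["pose"]
            if "nucleosome_area_range" in pose:
                pose["nucleosome_area_range"] = tuple(pose["nucleosome_area_range"])
            d["pose"] = PoseParams(**pose)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
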