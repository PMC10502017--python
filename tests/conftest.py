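import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from origamiflex import SimulationConfig, generate_micrograph

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

warnings.filterwarnings("ignore", category=FutureWarning, module="skimage")


@pytest.fixture(scope="session")
def small_scene():
    """One modest synthetic micrograph with all particle classes."""
    config = SimulationConfig(seed=11)
    micrograph, records = generate_micrograph(config)
    return config, micrograph, records


@pytest.fixture(scope="session")
def clean_single_hinge():
    """A noise-free scene containing exactly one isolated hinge."""
    config = SimulationConfig(
        seed=3,
        n_target_hinges=1,
        n_vertical_distractors=0,
        n_aggregates=0,
        n_free_blobs=0,
        n_boundary_fragments=0,
        noise_sd=0.0,
        mottle_sd=0.0,
    )
    micrograph, records = generate_micrograph(config)
    return config, micrograph, records


def hinge_pose(particle_id, schema, tip_a, vertex, tip_b, confs=(1.0, 1.0, 1.0)):
    """Convenience constructor for hinge-family test poses."""
    from origamiflex import KeypointPose, Point2D

    return KeypointPose(
        particle_id=particle_id,
        schema=schema,
        points={
            "tip_a": (Point2D(*tip_a), confs[0]),
            "vertex": (Point2D(*vertex), confs[1]),
            "tip_b": (Point2D(*tip_b), confs[2]),
        },
    )
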