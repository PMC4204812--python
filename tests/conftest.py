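import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import motionqc as mq
from motionqc.synth import PhantomConfig, synthetic_brain

settings.register_profile(
    "default",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sphere_shell_65():
    """Spherical gray-matter shell of radius 65 mm, 1 mm isotropic, centered."""
    cfg = PhantomConfig(
        shape=(141, 141, 141),
        semi_axes_mm=(65.0, 65.0, 65.0),
        shell_thickness_mm=3.0,
        contrast=0.0,
        texture_amplitude=0.0,
    )
    _, _, shell = synthetic_brain(cfg)
    return shell


@pytest.fixture(scope="session")
def small_brain():
    """32-voxel cube ellipsoidal brain phantom with texture (for replay tests)."""
    cfg = PhantomConfig(
        shape=(32, 32, 32),
        semi_axes_mm=(12.0, 11.0, 10.0),
        shell_thickness_mm=3.0,
        contrast=1.0,
        texture_amplitude=0.3,
        seed=1,
    )
    return synthetic_brain(cfg)


@pytest.fixture(scope="session")
def drifting_params():
    """A mixed drift + spike trajectory with non-trivial rotations."""
    from motionqc.synth import MotionSimConfig, simulate_motion

    params, _ = simulate_motion(
        MotionSimConfig(n_volumes=120, spike_probability=0.05, seed=42)
    )
    return params


def pure_rotation_params(t=40, amplitude=0.01, seed=0):
    rng = np.random.default_rng(seed)
    vals = np.zeros((t, 6))
    vals[1:, 3:] = rng.normal(0.0, amplitude, (t - 1, 3))
    return mq.RealignmentParams(vals)


def pure_translation_params(t=40, amplitude=0.5, seed=0):
    rng = np.random.default_rng(seed)
    vals = np.zeros((t, 6))
    vals[1:, :3] = rng.normal(0.0, amplitude, (t - 1, 3))
    return mq.RealignmentParams(vals)
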