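import numpy as np
import pytest

from swaylab import COPTrajectory, CohortSpec, SwayParams


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def gaussian_traj(rng):
    """Isotropic Gaussian COP cloud, 10,000 points, sigma = 1 mm."""
    return COPTrajectory(
        ml=rng.standard_normal(10_000),
        ap=rng.standard_normal(10_000),
        fs=200.0,
    )


@pytest.fixture
def scaled_params():
    """Duration-preserving scaled trial: 50 s at 10 Hz (500 samples)."""
    return SwayParams(fs=10.0, duration_s=50.0, resp_amp=0.0)


@pytest.fixture
def scaled_null_spec(scaled_params):
    """Scaled cohort with every condition contrast switched off."""
    return CohortSpec(
        baseline=scaled_params,
        group_effect=1.0,
        vision_effect=1.0,
        fp_effects={"FP20": 1.0, "FP10": 1.0, "FP30": 1.0},
        group_vision_interaction=1.0,
    )
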