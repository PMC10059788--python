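import numpy as np
import pytest

from coddetect import NoiseModel, TrialSpec, simulate_trial


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def quiet_noise():
    """Noise-free variant: pure kinematics, no gait, no sensor noise."""
    return NoiseModel(step_amp_g=0.0, white_sd_g=0.0, heading_noise_deg=0.0)


@pytest.fixture(scope="session")
def sample_trial(default_noise):
    """One 90-degree right turn at 13 km/h with the default noise model."""
    spec = TrialSpec(speed_kmh=13.0, angle_deg=90.0, direction="right", seed=7)
    return simulate_trial(spec, default_noise)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
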