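import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import linacvsm as lv

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def beam_params():
    return lv.SyntheticBeamParams(n=200_000, seed=1)


@pytest.fixture(scope="session")
def synthetic_set(beam_params):
    """Reference synthetic phase space shared across the suite."""
    return lv.make_synthetic_phsp(beam_params)


@pytest.fixture(scope="session")
def vsm(synthetic_set):
    """Source model built from the shared synthetic set."""
    return lv.build_vsm(synthetic_set, sou_n=200_000, sou_seed=3)


@pytest.fixture(scope="session")
def sou_cal():
    return lv.calibrate(seed=11, n=100_000)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
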