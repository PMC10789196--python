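import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icpolarity.head_model import HeadModel, standard_62_montage

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")

#: Canonical seed used throughout the suite for single-instance checks.
SUITE_SEED = 0


@pytest.fixture(scope="session")
def montage62():
    return standard_62_montage()


@pytest.fixture(scope="session")
def head_model():
    return HeadModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)


def upper_hemisphere_direction(rng):
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    d[2] = abs(d[2])
    return d / np.linalg.norm(d)
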