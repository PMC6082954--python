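import numpy as np
import pytest
from hypothesis import settings

from myoctl import simulate

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def acq():
    return simulate.AcquisitionConfig()


@pytest.fixture
def threshold_model():
    return simulate.default_threshold_model()


@pytest.fixture
def pattern_model():
    return simulate.default_pattern_model()
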