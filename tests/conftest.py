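import numpy as np
import pytest

from transdimer.smfs import BellEvansParams, FJCParams, PullingConfig
from transdimer.synthdata import DEFAULT_TETHER


@pytest.fixture
def tether():
    return DEFAULT_TETHER


@pytest.fixture
def high_state():
    return BellEvansParams(tau0=1224.2, x_beta=0.31)


@pytest.fixture
def low_state():
    return BellEvansParams(tau0=1.86, x_beta=0.55)


@pytest.fixture
def pull():
    return PullingConfig(kc=20.0, v=2000.0)


@pytest.fixture
def noiseless_pull():
    return PullingConfig(kc=20.0, v=2000.0, noise_sd=0.0)
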