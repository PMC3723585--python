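import numpy as np
import pytest

from cyclescope.simkit import SimConfig


@pytest.fixture
def cfg_noiseless() -> SimConfig:
    """Canonical conditions without measurement noise."""
    return SimConfig(noise_var=0.0)


@pytest.fixture
def cfg() -> SimConfig:
    """Canonical simulation conditions."""
    return SimConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
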