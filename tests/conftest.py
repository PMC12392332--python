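import numpy as np
import pytest
from hypothesis import settings

from fgrscreen.cohort_sim import SimConfig

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def config():
    """Default study configuration with a fixed seed."""
    return SimConfig(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
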