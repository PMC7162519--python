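import numpy as np
import pytest
from hypothesis import settings

from cointsim.dgp import DGPSpec, simulate_system

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def ci1_series():
    """A cointegrated pair with known beta0 = -1, T = 200."""
    return simulate_system(DGPSpec("CI1", T=200, seed=1234))


@pytest.fixture
def seed_stream():
    """Factory for independent, reproducible child seeds."""

    def make(n, entropy=99):
        return np.random.SeedSequence(entropy).spawn(n)

    return make
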