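import numpy as np
import pytest

from actipoly import SimulationParameters, build_random_melt
from actipoly.equilibration import soft_pushoff


@pytest.fixture(scope="session")
def small_params():
    return SimulationParameters(N=6, Np=20, seed=42)


@pytest.fixture(scope="session")
def small_melt(small_params):
    """A pushed-off (overlap-free) melt reused across read-only tests."""
    cfg = build_random_melt(small_params)
    return soft_pushoff(cfg, small_params, ramp_steps=15_000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
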