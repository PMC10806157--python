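import numpy as np
import pytest

from ippgsim.config import SimulationConfig
from ippgsim.pipeline import simulate_cube


@pytest.fixture(scope="session")
def stable_cube_30s():
    """A 30-s stable-scenario cube reused by the closed-loop method tests."""
    cfg = SimulationConfig(duration=30.0, width=32, height=32, hr=72.0, seed=3)
    return simulate_cube(cfg, quantize_8bit=True)


@pytest.fixture(scope="session")
def stable_cube_config():
    return SimulationConfig(duration=30.0, width=32, height=32, hr=72.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
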