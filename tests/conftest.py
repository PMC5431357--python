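import numpy as np
import pytest

from loopwaves import ModelParams


@pytest.fixture
def wave_params() -> ModelParams:
    """The canonical wave-state operating point (theta = 0.6)."""
    return ModelParams(r=1.0, rho=1.0, mu=1.8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def wave_sim():
    """One decently long wave-state realization, shared across tests."""
    from loopwaves import simulate

    params = ModelParams(r=1.0, rho=1.0, mu=1.8)
    return simulate(params, [3000, 3000, 3000], 80.0, seed=2, sample_dt=0.05)
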