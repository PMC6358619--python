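import numpy as np
import pytest

from plastlife import EnvParams, LifeHistoryParams, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def tiny_config():
    """A fast configuration for engine-level tests."""
    return SimConfig(N=100, t_max=200, env=EnvParams(p=0.5), epsilon=0.0,
                     seed=7, u_init=1.0, r_init=4.0, record_every=10)
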