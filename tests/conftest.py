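import numpy as np
import pytest

from lungseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_cfg():
    """Default-geometry phantoms at a small side for fast tests."""
    return PhantomConfig(side=128, seed=7)


@pytest.fixture(scope="session")
def phantom_pair(phantom_cfg):
    return generate_phantom(phantom_cfg, 0)


def set_all_params_zero(module):
    for p in module.parameters():
        p.data[...] = 0.0
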