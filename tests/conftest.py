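import numpy as np
import pytest

from lncdis import RunConfig
from lncdis.pipeline import build_network
from lncdis.synthetic import TINY, generate


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate(TINY, seed=7)


@pytest.fixture(scope="session")
def tiny_config():
    return RunConfig(embed_dim=6, embed_dim_low=3, max_iterations=150, random_seed=7)


@pytest.fixture(scope="session")
def tiny_network(tiny_bundle, tiny_config):
    return build_network(tiny_bundle, tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
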