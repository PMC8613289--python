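import numpy as np
import pytest

import nucactin as na


@pytest.fixture(scope="session")
def config():
    return na.load_config()


@pytest.fixture(scope="session")
def params(config):
    return config.params


@pytest.fixture(scope="session")
def geometry(config):
    return config.geometry


@pytest.fixture(scope="session")
def toy_domain(geometry):
    return na.build_domain(geometry, 41, 41)


@pytest.fixture(scope="session")
def random_state(toy_domain):
    return na.make_random_state(toy_domain, na.FixtureSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
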