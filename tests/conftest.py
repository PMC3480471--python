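import numpy as np
import pytest

from ecoclim import date_palm_defaults, make_world


@pytest.fixture(scope="session")
def palm():
    return date_palm_defaults()


@pytest.fixture(scope="session")
def small_world():
    """12x24 synthetic world shared by grid-level tests."""
    return make_world(n_lat=12, n_lon=24, seed=7)


@pytest.fixture(scope="session")
def world_36x72():
    """The packaged full-size synthetic world."""
    return make_world(n_lat=36, n_lon=72, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
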