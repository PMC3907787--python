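import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from ppitype.structure import default_table
from ppitype.synthetic import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grid_complex():
    """3x3 aligned grids, spacing 10 Å, gap 6 Å, alternating unit charges."""
    return make_toy_complex(ToyComplexSpec(n_side=3, spacing=10.0, gap=6.0))


@pytest.fixture(scope="session")
def jittered_complex():
    """A denser, jittered toy complex with many cross-chain contacts."""
    return make_toy_complex(ToyComplexSpec(n_side=5, spacing=4.0, gap=4.0,
                                           jitter=0.5, charge_plan="random",
                                           seed=7))
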