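import numpy as np
import pytest

from nanotherm import bioheat
from nanotherm.materials import get_material


@pytest.fixture(scope="session")
def gold():
    return get_material("gold")


@pytest.fixture(scope="session")
def water():
    return get_material("water")


@pytest.fixture()
def small_grid():
    """Coarse but valid tumor/tissue grid for fast solver tests."""
    return bioheat.RadialGrid.make(r_max=6e-3, tumor_radius=3e-3, n_nodes=81)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
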