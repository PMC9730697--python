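import numpy as np
import pytest

from rcsaem.grid_spline import build_basis, build_grid


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture(scope="session")
def basis63(grid):
    return build_basis(grid, knots=6, degree=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
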