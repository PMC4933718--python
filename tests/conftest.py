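import numpy as np
import pytest

import biovolt as bv
from biovolt.params import ParameterSet

# silence benign overflow warnings from saturating exponentials in sweeps
np.seterr(over="ignore", invalid="ignore")


@pytest.fixture(scope="session")
def disc_grid():
    """Medium disc cluster used by several geometry/operator tests."""
    mask = bv.disc_mask(90e-6, n_pixels=120)
    grid = bv.build_cell_grid(mask, 5e-6, rng_seed=1)
    return mask, grid


@pytest.fixture(scope="session")
def env20(disc_grid):
    mask, grid = disc_grid
    return bv.build_env_grid(mask.extent, 20, grid)


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def single_cell_world():
    world, cfg = bv.generate_fixture("single_cell", 0)
    return world


@pytest.fixture(scope="session")
def hex7_world():
    world, cfg = bv.generate_fixture("hex7", 0)
    return world
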