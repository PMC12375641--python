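import numpy as np
import pytest

from radioplan.grids import DoseGrid, StructureMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_uniform(dose=5000.0, shape=(5, 5, 4), spacing=(2.0, 2.0, 2.5)):
    """Uniform dose over the whole grid; mask covers everything."""
    grid = DoseGrid(np.full(shape, dose), spacing)
    mask = StructureMask("PTV", np.ones(shape, bool), spacing)
    return grid, mask


def make_ramp(low=0.0, high=6000.0, n=200, spacing=(1.0, 1.0, 1.0)):
    """Linear dose ramp along the first axis of an (n, 1, 1) box."""
    values = np.linspace(low, high, n).reshape(n, 1, 1)
    grid = DoseGrid(values, spacing)
    mask = StructureMask("ramp", np.ones((n, 1, 1), bool), spacing)
    return grid, mask


@pytest.fixture
def uniform_case():
    return make_uniform()


@pytest.fixture
def ramp_case():
    return make_ramp()
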