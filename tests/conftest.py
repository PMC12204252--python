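import numpy as np
import pytest

from ofc_biosig.bfmm import build_bspline_basis
from ofc_biosig.containers import TimeFreqGrid


@pytest.fixture(scope="session")
def grid():
    return TimeFreqGrid.default()


@pytest.fixture(scope="session")
def basis(grid):
    return build_bspline_basis(grid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
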