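import numpy as np
import pytest

from ki67topo.datatypes import CellPattern
from ki67topo import synth


@pytest.fixture(scope="session")
def csr_pattern():
    return synth.gen_pattern("csr", (1000.0, 1000.0), seed=11, n_points=400)


@pytest.fixture(scope="session")
def small_pattern():
    return synth.gen_pattern("csr", (500.0, 500.0), seed=7, n_points=60)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_pattern(points, window=(1000.0, 1000.0), **kw):
    return CellPattern(np.asarray(points, dtype=float), window_um=window, **kw)
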