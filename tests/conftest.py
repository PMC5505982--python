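import numpy as np
import pytest

from pstfst.popgen import GenotypeMatrix
from pstfst.simulate import SimConfig, gen_genotypes, gen_necrosis


@pytest.fixture
def toy_wc():
    """Single-locus worked example: pool1 = {1/1, 1/2}, pool2 = {2/2, 1/2}."""
    calls = np.array([[[1, 1]], [[1, 2]], [[2, 2]], [[1, 2]]])
    return GenotypeMatrix(["a", "b", "c", "d"], ["L1"], calls,
                          np.array(["p1", "p1", "p2", "p2"], dtype=object))


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=123)


@pytest.fixture(scope="session")
def default_genotypes(default_config):
    return gen_genotypes(default_config)


@pytest.fixture(scope="session")
def default_panel(default_config):
    return gen_necrosis(default_config)
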