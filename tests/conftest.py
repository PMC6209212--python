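import numpy as np
import pytest

from drivespread.diffusion_fem import build_three_block_mesh
from drivespread.genetics import mcr_frequencies, mendelian_frequencies
from drivespread.reaction import ModelParameters


@pytest.fixture(scope="session")
def params():
    """Default vital rates: eps=5.1, delta1=3.9, delta2=0.5, C=2500."""
    return ModelParameters()


@pytest.fixture(scope="session")
def mendel():
    return mendelian_frequencies()


@pytest.fixture(scope="session")
def mcr14():
    return mcr_frequencies(0.14)


@pytest.fixture(scope="session")
def release_mesh():
    """The default three-block 78-node linear mesh on [0, 30] km."""
    return build_three_block_mesh()


@pytest.fixture
def rng():
    return np.random.default_rng(20181031)
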