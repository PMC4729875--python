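import numpy as np
import pytest

from retrocall import default_library
from retrocall.simulate import SimConfig, generate_genome


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(genome_length=240_000, n_chromosomes=2, n_genes=0, seed=11)


@pytest.fixture(scope="session")
def genome(sim_config):
    return generate_genome(sim_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20_16)
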