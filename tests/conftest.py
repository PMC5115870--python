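import numpy as np
import pytest

from aluforge.synthetic import SimulationConfig, make_genome


@pytest.fixture(scope="session")
def small_dataset():
    """A modest noise-free-discovery dataset shared by read-only tests."""
    return make_genome(SimulationConfig(seed=11, n_genes=25))


@pytest.fixture(scope="session")
def rich_dataset():
    """Dataset with every intron carrying an insertion and all exonising."""
    cfg = SimulationConfig(
        seed=4, n_genes=20, alu_insertion_rate=1.0, exonisation_rate=1.0,
        sense_rate=0.0,
    )
    return make_genome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


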