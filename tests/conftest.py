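import numpy as np
import pytest

from dmrlink import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic world shared across tests."""
    cfg = SimConfig(seed=7, n_genes=100, n_chromosomes=2, chrom_length=1_100_000)
    return simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
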