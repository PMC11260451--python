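import numpy as np
import pytest

from ctdna_integrate.genomes import GenomeSequence, random_sequence
from ctdna_integrate.simulate import SimulationConfig, simulate_ctdna, simulate_genomes


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """One 20 kb contig: the smallest genome the generator accepts."""
    return SimulationConfig(n_contigs=1, contig_length=20_000, n_fragments=6)


@pytest.fixture(scope="session")
def small_world(small_config):
    """(cell, donor, library, fragments) on the small genome, seed 7."""
    cell, donor, library = simulate_genomes(small_config, seed=7)
    fragments = simulate_ctdna(
        donor, library, small_config.n_fragments,
        te_end_probability=1.0, seed=8, tissue="MM",
    )
    return cell, donor, library, fragments


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def toy_genome():
    g = np.random.default_rng(3)
    return GenomeSequence("cell", {"chr1": random_sequence(30_000, g)}, role="cell")
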