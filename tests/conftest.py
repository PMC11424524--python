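import numpy as np
import pytest

from plastrecon import PlastomeSequence, SimulationConfig, simulate_plastome

SMALL_CFG = SimulationConfig(lsc_len=2000, ssc_len=500, ir_len=800,
                             homopolymer_enrichment=10.0, rng_seed=42)


@pytest.fixture(scope="session")
def small_genome():
    """A 4.1 kb quadripartite genome with planted runs (deterministic)."""
    return simulate_plastome(SMALL_CFG)


@pytest.fixture(scope="session")
def small_plastome(small_genome):
    return PlastomeSequence("small", small_genome.sequence, circular=True,
                            partition=small_genome.partition)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))
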