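import numpy as np
import pytest

from ighdkit.cluster_architecture import call_genes, segment_clusters
from ighdkit.synthetic_locus import SimParams, simulate, simulate_ancestor

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, n)].tobytes().decode()


@pytest.fixture(scope="session")
def sim_locus():
    """One evolved locus (seed 7) with its truth log."""
    params = SimParams(seed=7)
    locus, truth = simulate(params)
    return params, locus, truth


@pytest.fixture(scope="session")
def sim_clusters(sim_locus):
    params, locus, truth = sim_locus
    genes = call_genes(locus, max_heptamer_mm=0, max_nonamer_mm=0)
    clusters = segment_clusters(locus, genes)
    return params, locus, truth, clusters


@pytest.fixture(scope="session")
def sim_ancestor():
    params = SimParams(seed=3)
    seq, truth = simulate_ancestor(params)
    return params, seq, truth
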