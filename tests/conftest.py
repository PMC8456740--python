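import numpy as np
import pytest

from endoepi.genome_io import GenomeSequence, GenomicInterval, GeneModel
from endoepi.simulate import SimulationConfig, simulate_genome, simulate_methylome


@pytest.fixture
def tiny_genome():
    # chr1 holds one forward motif (1-8) and one reverse-complement motif (9-16)
    return GenomeSequence({"chr1": "CTCTGTTTAAACAGAG", "chr2": "ACGTACGTACGT"})


@pytest.fixture
def whole_chr1_gene():
    return GeneModel("g1", GenomicInterval("chr1", 1, 16, "+"), 1)


@pytest.fixture(scope="session")
def small_dataset():
    """A seeded synthetic study small enough for per-test use: genome,
    genes, truth, site registry, mark domains and a 2-replicate methylome."""
    config = SimulationConfig(n_k27_only=60, n_k9_only=60, n_k27_k9=60, n_unmarked=120)
    genome, genes, truth, registry, domains = simulate_genome(config, seed=1)
    methylome = simulate_methylome(truth, genome, genes, registry, seed=1)
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "registry": registry,
        "domains": domains,
        "methylome": methylome,
    }
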