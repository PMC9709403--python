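import numpy as np
import pytest

from polyatac.io_formats import ChromSizes, GeneModel, Peak, TagRecord
from polyatac.simulate import SimConfig, simulate_library


@pytest.fixture
def toy_sizes():
    return ChromSizes({"chr1A": 50_000, "chrMt": 5_000})


@pytest.fixture
def small_genome():
    return ChromSizes({"chr1": 10_000})


def make_tags(chrom, positions, strand="+", mapq=60, length=50):
    """Tags with the given 5' cut coordinates."""
    out = []
    for p in positions:
        if strand == "+":
            out.append(TagRecord(chrom, p, p + length, "+", mapq))
        else:
            out.append(TagRecord(chrom, p - length + 1, p + 1, "-", mapq))
    return out


@pytest.fixture
def uniform_tags(toy_sizes):
    rng = np.random.default_rng(0)
    pos = rng.integers(100, toy_sizes["chr1A"] - 100, size=2_000)
    return make_tags("chr1A", sorted(int(p) for p in pos))


@pytest.fixture(scope="session")
def sim_small():
    """A scaled-down simulated library usable by many tests (session-scoped)."""
    config = SimConfig(
        seed=11,
        chromosomes=(("chr1A", 400_000), ("chrMt", 40_000)),
        n_genes=40,
        n_distal_peaks=5,
        n_fragments=30_000,
        contamination_rate=0.05,
    )
    return simulate_library(config)


@pytest.fixture
def plus_gene():
    return GeneModel("geneA", "chr1", 10_000, 15_000, "+")


@pytest.fixture
def minus_gene():
    return GeneModel("geneB", "chr1", 8_000, 10_001, "-")
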