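import pytest

from te_stress.annotations import GeneModel, GenomicInterval, TEInsertion
from te_stress.synthetic import SimulationConfig, generate_counts, generate_genome


def make_gene(gene_id="g1", chrom="chr1", start=100, end=200, strand="+", exons=None):
    iv = GenomicInterval(chrom, start, end, strand)
    return GeneModel(gene_id, iv, exons or [])


def make_te(te_id="te1", family="naiba", chrom="chr1", start=500, end=900,
            strand="+", superfamily="RLX"):
    return TEInsertion(te_id, family, superfamily, GenomicInterval(chrom, start, end, strand))


@pytest.fixture(scope="session")
def small_config():
    """A quick-to-simulate genome retaining the default effect structure."""
    return SimulationConfig(seed=11, n_genes=800, n_chromosomes=2)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_counts(small_genome):
    return generate_counts(small_genome)
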