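import numpy as np
import pytest

from paskit.models import GeneModel
from paskit.synthetic_data import simulate_genome, simulate_nascent_coverage


@pytest.fixture(scope="session")
def small_genome():
    """50-gene toy genome with truth, reused across read-only tests."""
    return simulate_genome(50, frac_pas=0.3, seed=11)


@pytest.fixture(scope="session")
def small_coverage(small_genome):
    genes, truth = small_genome
    return simulate_nascent_coverage(genes, truth, "22C", depth=10.0, seed=5)


@pytest.fixture()
def plus_gene():
    return GeneModel(gene_id="gp", chrom="chr1", start=1000, end=2000, strand="+")


@pytest.fixture()
def minus_gene():
    return GeneModel(gene_id="gm", chrom="chr1", start=1000, end=2000, strand="-")
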