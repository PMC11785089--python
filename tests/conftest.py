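import numpy as np
import pytest

from editome_kit import (
    EditModel,
    GenomeConfig,
    generate_genome,
    plant_truth,
)

TINY_GENOME = GenomeConfig(
    n_contigs=2,
    contig_length=6_000,
    n_genes=6,
    n_repeats=12,
    gene_length_range=(400, 700),
    intergenic_gap_range=(50, 250),
    n_exons_range=(2, 3),
)

# expression fixture: ISGs a small slice of a larger transcriptome, as in a
# genome-scale library, so per-million normalization is not dominated by the
# induced genes themselves
EXPR_GENOME = GenomeConfig(
    n_contigs=2,
    contig_length=250_000,
    n_genes=1_000,
    isg_fraction=0.04,
    n_repeats=0,
    gene_length_range=(300, 500),
    intergenic_gap_range=(30, 120),
    n_exons_range=(2, 2),
)

TINY_EDITS = EditModel(
    wt_sites=40,
    adar_het_sites=40,
    rdrp_tg_sites=40,
    double_het_ratio=1.5,
)


@pytest.fixture(scope="session")
def tiny_genome():
    return generate_genome(TINY_GENOME, seed=7)


@pytest.fixture(scope="session")
def expr_genome():
    return generate_genome(EXPR_GENOME, seed=17)


@pytest.fixture(scope="session")
def tiny_truth(tiny_genome):
    return plant_truth(tiny_genome, TINY_EDITS, snp_count=15, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
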