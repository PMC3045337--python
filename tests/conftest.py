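import numpy as np
import pytest

from genewin import simdata


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully featured study: 2 chromosomes, genes with exons, LD."""
    return simdata.SimConfig(
        seed=42, n_cases=150, n_controls=150, n_chromosomes=2,
        chrom_length_bp=4_000_000, n_genes=60, n_snps=600,
        missing_rate=0.01,
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return simdata.simulate_annotation(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_annotation):
    genes, snps = small_annotation
    cohort, truth = simdata.simulate_cohort(small_config, genes, snps)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
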