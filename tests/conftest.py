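import numpy as np
import pytest

from bgsinfer import (
    GammaDFE,
    MatingSystem,
    PiecewiseHistory,
    SFSModelConfig,
    ToyGenomeConfig,
    make_toy_genome,
)


@pytest.fixture(scope="session")
def small_genome():
    """Two chromosomes, 100 windows: quick analytic checks."""
    cfg = ToyGenomeConfig(
        n_chromosomes=2, chrom_length=500_000, selected_fraction=0.2,
        block_size=2_000, rate=1e-8, window_size=10_000, seed=3,
    )
    return make_toy_genome(cfg, mu=5.5e-9)


@pytest.fixture(scope="session")
def anchored_genome():
    """Recovery fixture: gene-density contrast plus a gene-free chromosome
    so that Nmax is identifiable from windows with B ~ 1."""
    cfg = ToyGenomeConfig(
        n_chromosomes=5, chrom_length=4_000_000, selected_fraction=0.25,
        block_size=2_000, rate=1.5e-8, window_size=10_000,
        density_amplitude=0.9, density_periods=2.0,
        gene_free_chromosomes=1, seed=7,
    )
    return make_toy_genome(cfg, mu=7.5e-9)


@pytest.fixture(scope="session")
def strong_dfe():
    return GammaDFE(7.5e-9, 0.01, 3.0)


@pytest.fixture(scope="session")
def fig1_dfe():
    return GammaDFE(5.5e-9, 0.0275, 0.55)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
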