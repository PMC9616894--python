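import pytest

from triohap.pipeline import compute_best_hit_tables
from triohap.synthetic import AncestorModel, HybridDesign, simulate_trio


@pytest.fixture(scope="session")
def small_model():
    """Desk-scale study: 2 chromosomes x 120 kbp, 50 genes per chromosome."""
    return AncestorModel(
        n_chromosomes=2, chrom_length=120_000, n_genes_per_chrom=50, seed=11
    )


@pytest.fixture(scope="session")
def small_trio(small_model):
    """Small trio with 3 injected switches per genome."""
    return simulate_trio(model=small_model, switches_per_genome=3)


@pytest.fixture(scope="session")
def clean_trio(small_model):
    """Same study without any injected switches."""
    return simulate_trio(model=small_model, switches_per_genome=0)


@pytest.fixture(scope="session")
def noise0_trio():
    """Trio with zero within-species haplotype noise: shared haplotypes
    across genomes are byte-identical."""
    model = AncestorModel(
        n_chromosomes=1, chrom_length=60_000, n_genes_per_chrom=25, seed=7
    )
    return simulate_trio(model=model, switches_per_genome=0, haplotype_noise_scale=0.0)


@pytest.fixture(scope="session")
def small_tables(small_trio):
    return compute_best_hit_tables(
        small_trio.assemblies, small_trio.catalogs, small_trio.design
    )


@pytest.fixture(scope="session")
def clean_tables(clean_trio):
    return compute_best_hit_tables(
        clean_trio.assemblies, clean_trio.catalogs, clean_trio.design
    )


@pytest.fixture
def triangle_design():
    return HybridDesign()
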