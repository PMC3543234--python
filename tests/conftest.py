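import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_genotype_dataset(
    rng: np.random.Generator,
    n_pops: int = 2,
    n_per_pop: int = 5,
    n_loci: int = 2,
    n_alleles: int = 3,
    missing_rate: float = 0.0,
):
    """Random diploid dataset with alleles drawn iid within populations."""
    from pollenseed.datasets import GenotypeDataset

    n = n_pops * n_per_pop
    geno = rng.integers(1, n_alleles + 1, size=(n, n_loci, 2))
    if missing_rate:
        miss = rng.random((n, n_loci)) < missing_rate
        geno[miss] = 0
    return GenotypeDataset(
        individual_id=[f"ind{i}" for i in range(n)],
        population=[f"pop{i // n_per_pop}" for i in range(n)],
        loci=[f"L{l}" for l in range(n_loci)],
        genotypes=geno,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_dataset(rng):
    return make_genotype_dataset(rng, n_pops=2, n_per_pop=8, n_loci=3)
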