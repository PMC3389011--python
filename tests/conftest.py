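import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_genome():
    """Small two-haplotype genome with SNPs, shared across tests."""
    from homopair import synthetic

    gen = np.random.default_rng(777)
    haplotypes, snps = synthetic.make_haplotype_genome(
        n_chroms=4, length=300_000, snp_rate=0.005, rng=gen
    )
    return haplotypes, snps


@pytest.fixture(scope="session")
def toy_fragments(toy_genome):
    from homopair import allelic4c

    haplotypes, _ = toy_genome
    return {
        allele: allelic4c.digest_genome(haplotypes[allele])
        for allele in allelic4c.ALLELES
    }
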