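import numpy as np
import pytest

from tmskit import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_ref():
    """50 kb single-chromosome reference with ~2% CpG density and probes."""
    return simulate.gen_reference(chrom_length=50_000, cpg_rate=0.02, seed=101)


@pytest.fixture(scope="session")
def two_group_truth(small_ref):
    """Ground truth over the first 300 reference CpGs with a 10% effect."""
    return simulate.simulate_truth(small_ref.sites[:300], delta=0.1, seed=102)


@pytest.fixture(scope="session")
def paired_tech_levels():
    """Two technology replicates of the same methylome for concordance
    tests: shared truth, independent count noise, sample-specific
    variation via between-sample overdispersion."""
    from tmskit import matrix

    sites = [simulate.CpGSite("chr1", 10 * i) for i in range(400)]
    truth = simulate.simulate_truth(
        sites, delta=0.0, frac_effect=0.0, sample_rho=0.10, coverage_mean=30, seed=103
    )
    mat_a, mat_b = simulate.gen_paired_technologies(truth, 8, seed=104)
    lev_a = matrix.methylation_levels(mat_a)
    lev_b = matrix.methylation_levels(mat_b)
    return lev_a, lev_b
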