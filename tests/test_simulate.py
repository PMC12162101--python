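import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, gaussian_kde

from tmskit import io, matrix
from tmskit.capture import proximity_mask
from tmskit.io import CpGSite
from tmskit.simulate import (
    DigestConfig,
    gen_array_betas,
    gen_count_matrix,
    gen_fragments,
    gen_methylome,
    gen_reference,
    gen_tissue_matrix,
    msp1_digest,
    simulate_truth,
)


class TestGenReference:
    def test_seed_determinism(self):
        a = gen_reference(chrom_length=5000, cpg_rate=0.02, seed=7)
        b = gen_reference(chrom_length=5000, cpg_rate=0.02, seed=7)
        assert a.fasta == b.fasta and a.sites == b.sites
        c = gen_reference(chrom_length=5000, cpg_rate=0.02, seed=8)
        assert c.fasta != a.fasta

    def test_zero_rate_means_no_cg(self):
        ref = gen_reference(chrom_length=3000, cpg_rate=0.0, seed=1)
        assert "CG" not in ref.genome["chr1"] and ref.sites == []

    def test_site_list_is_exactly_cg_occurrences(self, small_ref):
        for chrom, seq in small_ref.genome.items():
            scanned = {i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"}
            listed = {s.pos0 for s in small_ref.sites if s.chrom == chrom}
            assert scanned == listed

    def test_cpg_density_near_requested_rate(self, small_ref):
        rate = len(small_ref.sites) / sum(len(s) for s in small_ref.genome.values())
        assert rate == pytest.approx(0.02, rel=0.15)

    def test_every_probe_overlaps_a_cpg(self, small_ref):
        mask, _ = proximity_mask(small_ref.probes.intervals, [], tol=0)
        assert not mask.any()  # empty reference sanity
        # probe overlaps a CpG iff some site lies inside it
        site_mask, summ = proximity_mask(
            small_ref.probes.intervals,
            [io.GenomicInterval(s.chrom, s.pos0, s.pos0 + 2) for s in small_ref.sites],
            tol=0,
        )
        assert site_mask.all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_reference(cpg_rate=0.5)
        with pytest.raises(ValueError):
            gen_reference(chrom_length=10)


class TestGenMethylome:
    def test_no_effect_means_identical_group_truth(self, small_ref):
        truth = simulate_truth(small_ref.sites[:50], delta=0.0, frac_effect=0.0, seed=2)
        assert np.array_equal(truth.pi[0], truth.pi[1])

    def test_effect_sites_differ_by_exactly_delta(self, two_group_truth):
        eff = two_group_truth.effect_sites
        gap = two_group_truth.pi[1, eff] - two_group_truth.pi[0, eff]
        assert np.allclose(gap, 0.1)
        assert np.array_equal(
            two_group_truth.pi[0, ~eff], two_group_truth.pi[1, ~eff]
        )

    def test_coverage_mean_recovered(self):
        sites = [CpGSite("chr1", 2 * i) for i in range(500)]
        truth = simulate_truth(sites, delta=0.0, frac_effect=0.0, coverage_mean=20, seed=3)
        cm, _ = gen_count_matrix(truth, 15, seed=4)  # 15000 cells
        assert cm.coverage.mean() == pytest.approx(20, rel=0.05)

    def test_m_never_exceeds_coverage(self, two_group_truth):
        cm, _ = gen_count_matrix(two_group_truth, 4, seed=5)
        assert (cm.M <= cm.coverage).all() and (cm.M >= 0).all()

    def test_conversion_error_floor_and_chh_recovery(self):
        sites = [CpGSite("chr1", 2 * i) for i in range(300)]
        truth = simulate_truth(sites, delta=0.0, frac_effect=0.0, seed=6,
                               conversion_error=0.005, sample_rho=0.0)
        truth.pi[:] = 0.0  # fully unmethylated genome
        reports, _, _ = gen_methylome(truth, 4, seed=7, n_chh=400)
        m_cpg = u_cpg = m_chh = t_chh = 0
        for recs in reports.values():
            for r in recs:
                if r.context == "CpG":
                    m_cpg += r.M
                    u_cpg += r.M + r.U
                else:
                    m_chh += r.M
                    t_chh += r.M + r.U
        assert m_cpg / u_cpg == pytest.approx(0.005, rel=0.3)
        assert m_chh / t_chh == pytest.approx(0.005, rel=0.3)

    def test_reports_collapse_back_to_matrix(self, two_group_truth):
        reports, sheet, _ = gen_methylome(two_group_truth, 2, seed=8)
        collapsed = {s: io.collapse_strands(r) for s, r in reports.items()}
        cm = matrix.assemble_matrix(collapsed, sheet)
        assert cm.shape == (len(two_group_truth.sites), 4)

    def test_observed_methylation_bimodal(self):
        sites = [CpGSite("chr1", 2 * i) for i in range(800)]
        truth = simulate_truth(sites, delta=0.0, frac_effect=0.0, coverage_mean=30, seed=9)
        cm, _ = gen_count_matrix(truth, 6, seed=10)
        means = matrix.site_summary(matrix.methylation_levels(cm))["mean"].dropna()
        grid = np.linspace(0, 1, 201)
        dens = gaussian_kde(means)(grid)
        # local maxima of the kernel density
        modes = grid[1:-1][(dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])]
        assert any(m < 0.2 for m in modes) and any(m > 0.8 for m in modes)

    def test_effect_sites_need_headroom(self):
        sites = [CpGSite("chr1", 2 * i) for i in range(20)]
        with pytest.raises(ValueError, match="pi \\+ delta"):
            simulate_truth(sites, delta=0.9, frac_effect=1.0,
                           beta_low=(50, 1), beta_high=(50, 1), seed=11)


class TestArrayBetas:
    def test_noise_free_zero_offset_is_identity(self):
        m = np.linspace(0, 1, 11)
        assert np.allclose(gen_array_betas(m, offset=0.0, noise_sd=0.0), m)

    def test_positive_offset_caps_beta_below_one(self):
        m = np.ones(50)
        beta = gen_array_betas(m, offset=100.0, noise_sd=25.0, seed=1)
        assert (beta < 1.0).all()

    def test_seed_reproducibility(self):
        m = np.linspace(0, 1, 20)
        assert np.array_equal(
            gen_array_betas(m, seed=3), gen_array_betas(m, seed=3)
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_array_betas(np.array([0.5]), offset=-1.0)


class TestGenFragments:
    def test_all_on_target_when_prob_one(self, small_ref):
        frags = gen_fragments(small_ref.probes, 200, on_target_prob=1.0, seed=1)
        mask, _ = proximity_mask(frags, small_ref.probes.intervals, tol=200)
        assert mask.all()

    def test_observed_fraction_within_binomial_ci(self, small_ref):
        n = 10_000
        frags = gen_fragments(
            small_ref.probes, n, on_target_prob=0.785,
            genome_extent={"chr1": 200_000}, seed=2,
        )
        _, summ = proximity_mask(frags, small_ref.probes.intervals, tol=200)
        lo = binom.ppf(0.005, n, 0.785) / n
        hi = binom.ppf(0.995, n, 0.785) / n
        assert lo <= summ.fraction_on_target <= hi

    def test_zero_fragments_gives_empty_bed(self, small_ref):
        assert gen_fragments(small_ref.probes, 0, seed=3) == []

    def test_empty_probe_set_rejected(self):
        from tmskit.capture import ProbeSet

        with pytest.raises(ValueError):
            gen_fragments(ProbeSet([]), 10)


class TestMsp1Digest:
    def test_hand_worked_cut_positions(self):
        res = msp1_digest("TTCCGGAACCGGTT", DigestConfig(size_min=1, size_max=99))
        assert res.fragments == [(0, 3), (3, 9), (9, 14)]
        assert res.retained == res.fragments

    def test_no_motif_single_fragment(self):
        res = msp1_digest("ATATATAT", DigestConfig(size_min=1, size_max=99))
        assert res.fragments == [(0, 8)] and res.retained == [(0, 8)]

    def test_default_size_selection_rejects_short_toy(self):
        res = msp1_digest("TTCCGGAACCGGTT")
        assert res.retained == [] and res.covered_cpgs == []

    def test_covered_cpgs_only_on_retained_fragments(self):
        seq = "TTCCGGAA" + "A" * 200 + "CCGG" + "ACGT" * 50 + "CCGG" + "TT"
        res = msp1_digest(seq, DigestConfig(size_min=100, size_max=2000))
        for site in res.covered_cpgs:
            assert any(s <= site.pos0 < e for s, e in res.retained)
            assert seq[site.pos0 : site.pos0 + 2] == "CG"

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=300))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_fragments_partition_sequence(self, seq):
        res = msp1_digest(seq, DigestConfig(size_min=1, size_max=10_000))
        assert res.fragments[0][0] == 0 and res.fragments[-1][1] == len(seq)
        for (s1, e1), (s2, e2) in zip(res.fragments, res.fragments[1:]):
            assert e1 == s2

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DigestConfig(motif="")
        with pytest.raises(ValueError):
            DigestConfig(size_min=0)
        with pytest.raises(ValueError):
            DigestConfig(cut_offset=9)


def test_tissue_matrix_structure_and_planting():
    cm, planted = gen_tissue_matrix(n_sites=60, n_per_tissue=3, frac_effect=0.2, seed=1)
    assert cm.shape == (60, 18)
    assert planted.sum() == 12
    assert set(cm.meta["tissue"]) == {"adrenal", "heart", "kidney", "liver", "lung", "spleen"}
    with pytest.raises(ValueError):
        gen_tissue_matrix(n_sites=10, focal="brain", seed=2)
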