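import numpy as np
import pandas as pd
import pytest

from tmskit import simulate
from tmskit.io import CpGSite, GenomicInterval
from tmskit.matrix import (
    CountMatrix,
    FilterSpec,
    MethLevels,
    annotation_summary,
    assemble_matrix,
    filter_matrix,
    methylation_levels,
    promoters_from_tss,
    site_summary,
)

from .oracles import filter_brute


def _site(p):
    return CpGSite("chr1", p)


class TestAssemble:
    def test_union_of_sites_with_zero_fill(self):
        reports = {
            "a": {_site(10): (1, 2), _site(20): (3, 4), _site(30): (5, 6)},
            "b": {_site(10): (7, 8), _site(20): (9, 1)},
        }
        cm = assemble_matrix(reports)
        assert cm.shape == (3, 2)
        i = cm.sites.index(_site(30))
        j = cm.samples.index("b")
        assert cm.M[i, j] == 0 and cm.U[i, j] == 0

    def test_single_sample_reproduces_report(self):
        rep = {_site(5): (2, 3), _site(9): (0, 1)}
        cm = assemble_matrix({"only": rep})
        for site, (m, u) in rep.items():
            i = cm.sites.index(site)
            assert (cm.M[i, 0], cm.U[i, 0]) == (m, u)

    def test_sheet_mismatch_rejected(self):
        sheet = pd.DataFrame({"group": ["x"]}, index=["other"])
        with pytest.raises(ValueError, match="absent"):
            assemble_matrix({"a": {_site(1): (1, 1)}}, sheet)

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix([_site(1)], ["a", "a"], np.zeros((1, 2)), np.zeros((1, 2)))


class TestFilter:
    def _mat(self, coverages):
        """One matrix whose rows have the given per-sample coverages (all reads methylated)."""
        cov = np.asarray(coverages)
        return CountMatrix(
            [_site(10 * (i + 1)) for i in range(cov.shape[0])],
            [f"s{j}" for j in range(cov.shape[1])],
            cov,
            np.zeros_like(cov),
        )

    def test_default_rule_three_samples(self):
        cm = self._mat([[6, 6, 6], [6, 6, 0]])
        out, report = filter_matrix(cm, FilterSpec(min_cov=5, min_frac=0.75))
        assert [s.pos0 for s in out.sites] == [10]
        assert report["dropped_coverage"] == 1

    def test_relaxed_rule_keeps_two_of_three(self):
        cm = self._mat([[6, 6, 0]])
        out, _ = filter_matrix(cm, FilterSpec(min_cov=1, min_frac=2 / 3))
        assert out.shape[0] == 1

    def test_empty_matrix_passes_through(self):
        cm = CountMatrix([], ["a"], np.zeros((0, 1)), np.zeros((0, 1)))
        out, report = filter_matrix(cm, FilterSpec())
        assert out.shape == (0, 1) and report["n_kept"] == 0

    def test_target_filter_uses_proximity(self):
        cm = self._mat([[9], [9]])  # sites at 10 and 20
        spec = FilterSpec(min_cov=1, min_frac=0.5,
                          target=[GenomicInterval("chr1", 18, 25)], tol=0)
        out, report = filter_matrix(cm, spec)
        assert [s.pos0 for s in out.sites] == [20]
        assert report["dropped_off_target"] == 1

    @pytest.mark.parametrize("cov_cmp", ["ge", "gt"])
    @pytest.mark.parametrize("frac_cmp", ["ge", "gt"])
    def test_matches_brute_force_reference(self, rng, cov_cmp, frac_cmp):
        for _ in range(10):
            n_sites = int(rng.integers(1, 60))
            n_samples = int(rng.integers(1, 12))
            M = rng.integers(0, 8, size=(n_sites, n_samples))
            U = rng.integers(0, 8, size=(n_sites, n_samples))
            cm = CountMatrix([_site(2 * i) for i in range(n_sites)],
                             [f"s{j}" for j in range(n_samples)], M, U)
            spec = FilterSpec(min_cov=int(rng.integers(0, 10)),
                              min_frac=float(rng.random()),
                              cov_cmp=cov_cmp, frac_cmp=frac_cmp)
            out, _ = filter_matrix(cm, spec)
            want = filter_brute(M, U, spec.min_cov, spec.min_frac, cov_cmp, frac_cmp)
            assert [s.pos0 for s in out.sites] == [2 * i for i, k in enumerate(want) if k]

    def test_idempotent(self, rng):
        M = rng.integers(0, 10, size=(40, 6))
        U = rng.integers(0, 10, size=(40, 6))
        cm = CountMatrix([_site(2 * i) for i in range(40)],
                         [f"s{j}" for j in range(6)], M, U)
        spec = FilterSpec()
        once, _ = filter_matrix(cm, spec)
        twice, _ = filter_matrix(once, spec)
        assert twice.sites == once.sites
        assert np.array_equal(twice.M, once.M)


class TestLevels:
    def test_levels_formula_and_missing(self):
        cm = CountMatrix([_site(1)], ["a", "b", "c"],
                         np.array([[5, 0, 3]]), np.array([[3, 0, 0]]))
        lv = methylation_levels(cm)
        assert lv.m[0, 0] == pytest.approx(0.625)
        assert np.isnan(lv.m[0, 1])
        assert lv.m[0, 2] == 1.0

    def test_converges_to_truth_at_high_coverage(self):
        sites = [_site(2 * i) for i in range(200)]
        truth = simulate.simulate_truth(sites, delta=0.0, frac_effect=0.0,
                                        coverage_mean=500, conversion_error=0.0,
                                        sample_rho=0.0, seed=21)
        cm, _ = simulate.gen_count_matrix(truth, 3, seed=22)
        lv = methylation_levels(cm)
        assert np.nanmax(np.abs(lv.m - truth.pi[0][:, None])) < 0.08
        assert np.nanmean(np.abs(lv.m - truth.pi[0][:, None])) < 0.02


class TestSiteSummary:
    def test_hand_example_with_missing(self):
        lv = MethLevels([_site(1)], ["a", "b", "c"],
                        np.array([[0.2, 0.4, np.nan]]))
        s = site_summary(lv)
        assert s.loc[0, "mean"] == pytest.approx(0.3)
        assert s.loc[0, "median"] == pytest.approx(0.3)
        assert s.loc[0, "n_observed"] == 2
        assert bool(s.loc[0, "variable"]) and bool(s.loc[0, "hypo"])

    def test_all_missing_site_has_unset_flags(self):
        lv = MethLevels([_site(1)], ["a"], np.array([[np.nan]]))
        s = site_summary(lv)
        assert np.isnan(s.loc[0, "mean"])
        assert not s.loc[0, ["variable", "hypo", "hyper"]].any()

    def test_variable_bounds_are_strict(self):
        lv = MethLevels([_site(1), _site(3)], ["a"], np.array([[0.9], [0.1]]))
        s = site_summary(lv)
        assert not s["variable"].any()


class TestAnnotationSummary:
    def test_per_label_counts_and_medians(self):
        sites = [_site(10), _site(20), _site(100)]
        medians = np.array([0.1, 0.3, 0.9])
        ann = {
            "A": [GenomicInterval("chr1", 0, 50)],
            "B": [GenomicInterval("chr1", 90, 110)],
        }
        out = annotation_summary(sites, medians, ann)
        assert out.loc["A", "n_sites"] == 2
        assert out.loc["A", "median_methylation"] == pytest.approx(0.2)
        assert out.loc["B", "n_sites"] == 1
        assert out.loc["unannotated", "n_sites"] == 0

    def test_no_annotations_everything_unannotated(self):
        out = annotation_summary([_site(1)], np.array([0.5]), {})
        assert out.loc["unannotated", "n_sites"] == 1

    def test_site_in_two_labels_counted_in_both(self):
        sites = [_site(10)]
        ann = {
            "A": [GenomicInterval("chr1", 0, 50)],
            "B": [GenomicInterval("chr1", 5, 15)],
        }
        out = annotation_summary(sites, np.array([0.4]), ann)
        assert out.loc["A", "n_sites"] == 1 and out.loc["B", "n_sites"] == 1
        assert out.loc["unannotated", "n_sites"] == 0

    def test_recovers_planted_hypo_hyper_ordering(self):
        # promoter-like region planted hypomethylated, quiescent-like hypermethylated
        rng = np.random.default_rng(31)
        promoter_sites = [_site(p) for p in range(100, 200, 2)]
        quiescent_sites = [_site(p) for p in range(1000, 1100, 2)]
        sites = promoter_sites + quiescent_sites
        medians = np.concatenate([
            rng.beta(1, 10, size=len(promoter_sites)),
            rng.beta(10, 1, size=len(quiescent_sites)),
        ])
        ann = {
            "promoter_like": [GenomicInterval("chr1", 100, 200)],
            "quiescent_like": [GenomicInterval("chr1", 1000, 1100)],
        }
        out = annotation_summary(sites, medians, ann)
        assert (
            out.loc["promoter_like", "median_methylation"]
            < out.loc["quiescent_like", "median_methylation"]
        )


def test_promoters_from_tss_strand_aware():
    tss = [
        GenomicInterval("chr1", 5000, 5001, strand="+"),
        GenomicInterval("chr1", 8000, 8001, strand="-"),
        GenomicInterval("chr1", 500, 501, strand="+"),  # clipped at origin
    ]
    out = promoters_from_tss(tss)
    assert GenomicInterval("chr1", 3000, 5000) in out
    assert GenomicInterval("chr1", 8001, 10001) in out
    assert GenomicInterval("chr1", 0, 500) in out


def test_tsv_round_trip(tmp_path):
    cm = CountMatrix([_site(2), _site(8)], ["a", "b"],
                     np.array([[1, 2], [3, 4]]), np.array([[5, 6], [7, 8]]))
    cm.to_tsv(tmp_path / "m.tsv", tmp_path / "u.tsv")
    back = CountMatrix.from_tsv(tmp_path / "m.tsv", tmp_path / "u.tsv")
    assert back.sites == cm.sites and back.samples == cm.samples
    assert np.array_equal(back.M, cm.M) and np.array_equal(back.U, cm.U)
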