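"""The combined mean-variance screen, K-S test, and pattern classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hepascreen.screen import (
    classify_pattern,
    contrast_key,
    fisher_combine,
    group_fold_change,
    ks_two_sample,
    mean_variance_test,
    screen_gene_set,
)
from tests.conftest import make_expression


class TestFoldChange:
    def test_mean_ratio_reproduces_published_style_value(self):
        # EPCAM-like constructed input: NOR mean 100, CIR mean 1480 -> 14.8
        expr = make_expression([[90, 100, 110, 1470, 1480, 1490]],
                               groups=["NOR"] * 3 + ["CIR"] * 3, genes=["EPCAM"])
        assert group_fold_change(expr, "EPCAM", "CIR") == pytest.approx(14.8)

    def test_identical_groups_give_unity(self):
        expr = make_expression([[5, 7, 5, 7]], groups=["NOR", "NOR", "CIR", "CIR"])
        assert group_fold_change(expr, "g0", "CIR") == pytest.approx(1.0)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(5, 1, (4, 10))
        groups = ["NOR"] * 4 + ["HCC_EARLY"] * 6
        expr = make_expression(vals, groups=groups)
        for i in range(4):
            oracle = vals[i, 4:].mean() / vals[i, :4].mean()
            assert group_fold_change(expr, f"g{i}", "HCC_EARLY") == pytest.approx(
                oracle, rel=1e-12)

    @given(c=st.floats(1.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_scaling_one_group_scales_fc_exactly(self, c):
        vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        expr = make_expression(vals, groups=["NOR"] * 3 + ["CIR"] * 3)
        base = group_fold_change(expr, "g0", "CIR")
        vals2 = vals.copy()
        vals2[0, 3:] *= c
        expr2 = make_expression(vals2, groups=["NOR"] * 3 + ["CIR"] * 3)
        assert group_fold_change(expr2, "g0", "CIR") == pytest.approx(
            base * c, rel=1e-12)


class TestMeanVarianceTest:
    def test_identical_samples_degenerate_case(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        p_t, p_f, p_comb = mean_variance_test(x, x)
        assert p_t == pytest.approx(1.0)
        assert p_f == pytest.approx(1.0)
        # Fisher combination of the observed pair
        assert p_comb == pytest.approx(
            float(stats.chi2.sf(-2 * (np.log(p_t) + np.log(p_f)), 4)))

    def test_fisher_combination_chi_square_oracle(self):
        # p_t = p_f = 0.05 -> X = -4 ln 0.05 = 11.98, chi2(4) tail ~ 0.0175
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.01748, abs=2e-4)

    def test_combined_p_uniform_under_independent_uniform_inputs(self):
        rng = np.random.default_rng(99)
        u = rng.uniform(size=(2, 10_000))
        p = fisher_combine(u)
        assert p.max() <= 1.0
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_variance_only_alternative_powers_combined_test(self):
        """sigma-ratio-2 alternative, n=12 vs 49: the combined test must
        reject at alpha=0.001 at least 5x as often as the t test alone."""
        rng = np.random.default_rng(4242)
        x = rng.normal(0, 1, size=(1000, 12))
        y = rng.normal(0, 2, size=(1000, 49))
        p_t, _, p_comb = mean_variance_test(x, y)
        t_rej = int((np.atleast_1d(p_t) < 0.001).sum())
        comb_rej = int((np.atleast_1d(p_comb) < 0.001).sum())
        assert comb_rej >= max(5 * t_rej, 10)

    def test_zero_variance_both_sides_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            _, p_f, _ = mean_variance_test([1.0, 1.0, 1.0], [2.0, 2.0])
        assert p_f == 1.0


def _ks_permutation_oracle(x, y, alternative):
    """Naive exhaustive relabeling oracle, statistic via direct ECDFs."""
    def stat(a, b):
        a, b = np.sort(a), np.sort(b)
        grid = np.concatenate([a, b])
        fa = np.searchsorted(a, grid, side="right") / a.size
        fb = np.searchsorted(b, grid, side="right") / b.size
        return (np.max(np.abs(fa - fb)) if alternative == "two_sided"
                else np.max(fb - fa))

    pooled = np.concatenate([x, y])
    n = len(x)
    obs = stat(np.asarray(x, float), np.asarray(y, float))
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        hits += stat(pooled[mask], pooled[~mask]) >= obs - 1e-12
        total += 1
    return obs, hits / total


class TestKSTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_disjoint_small_samples_exact_permutation(self):
        d, p = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0
        assert p == pytest.approx(0.1)  # 2 of 20 equal-size labelings reach D=1

    @pytest.mark.parametrize("n,m,alternative", [
        (3, 3, "two_sided"), (4, 5, "two_sided"), (2, 8, "two_sided"),
        (6, 6, "two_sided"), (3, 3, "greater"), (5, 4, "greater"),
        (6, 6, "greater"),
    ])
    def test_exact_small_sample_p_equals_permutation_oracle(self, n, m, alternative):
        rng = np.random.default_rng(n * 100 + m)
        for _ in range(3):
            x = rng.normal(size=n)
            y = rng.normal(0.5, 1.2, size=m)
            d, p = ks_two_sample(x, y, alternative)
            d_o, p_o = _ks_permutation_oracle(x, y, alternative)
            assert d == pytest.approx(d_o)
            assert p == pytest.approx(p_o)

    def test_exact_handles_ties(self):
        x = [1.0, 1.0, 2.0]
        y = [1.0, 2.0, 2.0]
        d, p = ks_two_sample(x, y)
        d_o, p_o = _ks_permutation_oracle(x, y, "two_sided")
        assert (d, p) == (pytest.approx(d_o), pytest.approx(p_o))

    def test_large_sample_null_calibration(self):
        rng = np.random.default_rng(7)
        rej = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=100)
            y = rng.normal(size=100)
            _, p = ks_two_sample(x, y)
            rej += p < 0.05
        assert 0.03 <= rej / reps <= 0.07

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=6),
           st.lists(st.floats(-5, 5), min_size=2, max_size=6))
    @settings(max_examples=30, deadline=None)
    def test_two_sided_is_symmetric_and_bounded(self, x, y):
        d1, p1 = ks_two_sample(x, y)
        d2, p2 = ks_two_sample(y, x)
        assert d1 == pytest.approx(d2)
        assert p1 == pytest.approx(p2)
        assert 0 <= p1 <= 1 and 0 <= d1 <= 1


class TestScreenGeneSet:
    def test_null_fixture_type_one_error(self):
        rng = np.random.default_rng(11)
        n_genes = 10_000
        vals = np.exp2(rng.normal(8, 0.5, (n_genes, 91)))
        groups = (["NOR"] * 12 + ["CIR"] * 30 + ["HCC_EARLY"] * 31
                  + ["HCC_LATE"] * 18)
        expr = make_expression(vals, groups=groups)
        res = screen_gene_set(expr, [f"g{i}" for i in range(n_genes)])
        for a, b in (("NOR", "CIR"), ("NOR", "HCC_EARLY"), ("CIR", "HCC")):
            frac = res[f"sig_{contrast_key(a, b)}"].mean()
            assert frac <= 0.003

    def test_single_gene_matches_direct_composition(self):
        rng = np.random.default_rng(12)
        vals = rng.lognormal(6, 0.5, (1, 91))
        groups = (["NOR"] * 12 + ["CIR"] * 30 + ["HCC_EARLY"] * 31
                  + ["HCC_LATE"] * 18)
        expr = make_expression(vals, groups=groups)
        res = screen_gene_set(expr, ["g0"])
        x = np.log2(vals[0, 12:42])
        y = np.log2(vals[0, :12])
        p_t, p_f, p_comb = mean_variance_test(x, y)
        key = contrast_key("NOR", "CIR")
        assert res.loc["g0", f"p_comb_{key}"] == pytest.approx(p_comb)
        assert res.loc["g0", f"fc_{key}"] == pytest.approx(
            group_fold_change(expr, "g0", "CIR"))

    def test_unknown_genes_warned_and_skipped(self):
        expr = make_expression(np.ones((2, 12)) * np.arange(1, 13),
                               groups=["NOR"] * 6 + ["CIR"] * 2
                               + ["HCC_EARLY"] * 2 + ["HCC_LATE"] * 2)
        with pytest.warns(UserWarning, match="nosuchgene"):
            res = screen_gene_set(expr, ["g0", "nosuchgene"])
        assert list(res.index) == ["g0"]


def _result_row(sig: dict, fc: dict) -> dict:
    row = {}
    contrasts = [("NOR", "CIR"), ("NOR", "HCC_EARLY"), ("NOR", "HCC_LATE"),
                 ("NOR", "HCC"), ("CIR", "HCC"), ("CIR", "HCC_EARLY"),
                 ("CIR", "HCC_LATE"), ("HCC_EARLY", "HCC_LATE")]
    for a, b in contrasts:
        k = contrast_key(a, b)
        row[f"sig_{k}"] = sig.get(k, False)
        row[f"fc_{k}"] = fc.get(k, 1.0)
    return row


class TestClassifyPattern:
    def test_epcam_like_profile_is_cirrhosis_peak(self):
        row = _result_row(
            sig={"NOR_vs_CIR": True, "NOR_vs_HCC_EARLY": True,
                 "NOR_vs_HCC_LATE": True, "CIR_vs_HCC": True,
                 "CIR_vs_HCC_LATE": True},
            fc={"NOR_vs_CIR": 14.8, "NOR_vs_HCC_EARLY": 14.0,
                "NOR_vs_HCC_LATE": 5.7, "NOR_vs_HCC": 10.9})
        assert classify_pattern(row) == "CIR_PEAK"

    def test_dkk1_like_profile_is_tumor_only(self):
        row = _result_row(
            sig={"NOR_vs_HCC_EARLY": True, "NOR_vs_HCC_LATE": True,
                 "CIR_vs_HCC": True},
            fc={"NOR_vs_HCC_EARLY": 3.8, "NOR_vs_HCC_LATE": 1.8,
                "NOR_vs_HCC": 3.0})
        assert classify_pattern(row) == "TUMOR_ONLY"

    def test_no_significance_is_unchanged(self):
        assert classify_pattern(_result_row({}, {})) == "UNCHANGED"

    def test_late_only(self):
        row = _result_row(sig={"NOR_vs_HCC_LATE": True},
                          fc={"NOR_vs_HCC_LATE": 2.0})
        assert classify_pattern(row) == "LATE_ONLY"

    def test_down_persistent(self):
        row = _result_row(sig={"NOR_vs_CIR": True, "NOR_vs_HCC": True},
                          fc={"NOR_vs_CIR": 0.5, "NOR_vs_HCC": 0.5})
        assert classify_pattern(row) == "DOWN_PERSISTENT"

    def test_shared_amplified_gpc3_like(self):
        row = _result_row(
            sig={"NOR_vs_CIR": True, "NOR_vs_HCC_EARLY": True,
                 "NOR_vs_HCC_LATE": True, "CIR_vs_HCC": True},
            fc={"NOR_vs_CIR": 2.0, "NOR_vs_HCC_EARLY": 7.2,
                "NOR_vs_HCC_LATE": 10.4, "NOR_vs_HCC": 8.0})
        assert classify_pattern(row) == "SHARED_AMPLIFIED"

    def test_every_gene_gets_exactly_one_label(self, mimic_expr, registry):
        res = screen_gene_set(mimic_expr, list(registry.liver_dev)[:40])
        from hepascreen.screen import PATTERN_LABELS
        assert res["pattern"].isin(PATTERN_LABELS).all()

    def test_mimic_cirrhosis_peak_genes_flagged_in_both_contrasts(
            self, mimic_expr):
        """Genes planted with the cirrhosis-peak profile must be significant
        both against normal and against the pooled tumors."""
        from hepascreen.registry import CIR_PEAK_FC

        res = screen_gene_set(mimic_expr, list(CIR_PEAK_FC))
        assert res[f"sig_{contrast_key('NOR', 'CIR')}"].all()
        assert res[f"sig_{contrast_key('CIR', 'HCC')}"].all()
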