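"""Group comparisons: Cohen's d, normality routing, ANCOVA, multiplicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import bbadkit as bk

from conftest import SEED, build_labeled


# printed group summaries (mean_neg, sd_neg, mean_pos, sd_pos) and the
# published pooled-SD effect size at n = 33 / 69
PRINTED_EFFECT_SIZES = [
    ("csf_ab42", 966.09, 410.34, 555.58, 220.33, -1.4),
    ("csf_ttau", 335.48, 139.22, 643.63, 294.15, 1.2),
    ("csf_ptau181", 39.26, 16.14, 113.60, 62.01, 1.4),
    ("plasma_ab42", 30.91, 7.51, 21.41, 9.56, -1.1),
    ("plasma_ptau181", 1.68, 0.64, 3.28, 1.77, 1.1),
    ("plasma_ptau217", 0.18, 0.11, 0.83, 0.56, 1.4),
]


class TestCohenD:
    @pytest.mark.parametrize("name,mn,sn,mp,sp,expected", PRINTED_EFFECT_SIZES)
    def test_reproduces_published_values(self, name, mn, sn, mp, sp, expected):
        eff = bk.cohen_d(mn, sn, 33, mp, sp, 69)
        assert round(eff.d, 1) == expected

    def test_equal_means_symmetric_ci(self):
        eff = bk.cohen_d(5.0, 1.0, 20, 5.0, 2.0, 30)
        assert eff.d == 0.0
        assert eff.ci95_low == pytest.approx(-eff.ci95_high)

    @given(st.floats(0.1, 100), st.floats(-5, 5))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_affine_invariance(self, scale, shift):
        base = bk.cohen_d(0.18, 0.11, 33, 0.83, 0.56, 69)
        scaled = bk.cohen_d(0.18 * scale + shift, 0.11 * scale, 33,
                            0.83 * scale + shift, 0.56 * scale, 69)
        assert scaled.d == pytest.approx(base.d, rel=1e-9)

    def test_degenerate_pooled_sd_errors(self):
        with pytest.raises(ValueError):
            bk.cohen_d(1.0, 0.0, 10, 1.0, 0.0, 10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            bk.cohen_d(1.0, 0.5, 1, 2.0, 0.5, 10)


class TestCompareGroups:
    def test_identical_groups_null_result(self):
        rng = np.random.default_rng(SEED)
        vals = rng.normal(10, 2, 40)
        cohort = build_labeled(40, 40, rng,
                               plasma_nfl=np.concatenate([vals, vals]))
        cmp_ = bk.compare_groups(cohort, "plasma_nfl")
        assert cmp_.effect.d == pytest.approx(0.0, abs=1e-12)
        assert cmp_.p_raw > 0.9

    def test_routing_normal_groups_use_t(self):
        rng = np.random.default_rng(SEED)
        cohort = build_labeled(50, 50, rng,
                               plasma_nfl=rng.normal(40, 5, 100))
        assert bk.compare_groups(cohort, "plasma_nfl").test_used == "t"

    def test_routing_heavy_lognormal_uses_wilcoxon(self):
        rng = np.random.default_rng(SEED)
        # sd/mean > 1: Shapiro-Wilk rejects with overwhelming probability
        vals = rng.lognormal(0.0, 1.2, 138)
        cohort = build_labeled(69, 69, rng, plasma_nfl=vals)
        assert bk.compare_groups(cohort, "plasma_nfl").test_used == "wilcoxon"

    def test_percent_median_difference(self):
        rng = np.random.default_rng(SEED)
        neg = np.array([1.9, 2.1] * 5)                      # median 2.0
        pos = np.array([4.9] * 7 + [5.0] + [5.1] * 7)       # median 5.0
        cohort = build_labeled(10, 15, rng,
                               plasma_ptau181=np.concatenate([neg, pos]))
        cmp_ = bk.compare_groups(cohort, "plasma_ptau181")
        assert cmp_.percent_median_diff == pytest.approx(150.0)

    def test_separated_groups_tiny_p(self):
        cfg = bk.default_config()
        cfg.n_neg = cfg.n_pos = 1000
        lab = bk.label_cohort(bk.generate_cohort(cfg, seed=SEED))
        cmp_ = bk.compare_groups(lab, "plasma_ptau217")
        assert cmp_.p_raw < 1e-10
        assert cmp_.percent_median_diff > 100

    def test_tiny_group_errors(self):
        rng = np.random.default_rng(SEED)
        cohort = build_labeled(2, 10, rng)
        with pytest.raises(ValueError):
            bk.compare_groups(cohort, "plasma_nfl")

    def test_sign_convention_matches_biology(self, labeled_cohort):
        # elevated in A+ -> d > 0; depressed in A+ -> d < 0
        assert bk.compare_groups(labeled_cohort, "csf_ptau181").effect.d > 0
        assert bk.compare_groups(labeled_cohort, "csf_ttau").effect.d > 0
        assert bk.compare_groups(labeled_cohort, "csf_ab42").effect.d < 0
        assert bk.compare_groups(labeled_cohort, "csf_ab42_40").effect.d < 0


class TestAncova:
    def test_unconfounded_adjustment_preserves_p(self):
        rng = np.random.default_rng(SEED)
        n = 2000
        age = rng.normal(70, 7, 2 * n)
        effect = np.concatenate([np.zeros(n), np.full(n, 0.8)])
        vals = 10 + effect + rng.normal(0, 1, 2 * n)
        cohort = build_labeled(n, n, rng, age=age, plasma_ptau181=vals)
        p_adj = bk.ancova_adjusted_p(cohort, "plasma_ptau181")
        p_raw = stats.ttest_ind(vals[n:], vals[:n]).pvalue
        # no confounding: both overwhelmingly significant
        assert p_adj < 1e-10 and p_raw < 1e-10

    def test_age_mediated_difference_vanishes_after_adjustment(self):
        rng = np.random.default_rng(SEED)
        n = 300
        age = np.concatenate([rng.normal(65, 3, n), rng.normal(75, 3, n)])
        vals = 0.5 * age + rng.normal(0, 0.5, 2 * n)  # group enters via age only
        cohort = build_labeled(n, n, rng, age=age, plasma_nfl=vals)
        p_adj = bk.ancova_adjusted_p(cohort, "plasma_nfl")
        p_raw = stats.ttest_ind(vals[n:], vals[:n]).pvalue
        assert p_raw < 1e-10
        # after adjustment the group effect is null: p far from the raw one
        assert p_adj > 1e6 * p_raw and p_adj > 1e-3

    def test_null_adjusted_p_uniform(self):
        rng = np.random.default_rng(SEED)
        ps = []
        for _ in range(200):
            vals = rng.normal(10, 2, 120)
            cohort = build_labeled(60, 60, rng, plasma_nfl=vals)
            ps.append(bk.ancova_adjusted_p(cohort, "plasma_nfl"))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_collinear_covariates_error_names_columns(self):
        rng = np.random.default_rng(SEED)
        cohort = build_labeled(20, 20, rng)
        cohort.df["age2"] = cohort.df["age"] * 2
        with pytest.raises(ValueError, match="collinear"):
            bk.ancova_adjusted_p(cohort, "plasma_nfl",
                                 covariates=("age", "age2"))


class TestAdjustPvalues:
    def test_bh_step_up_hand_computed(self):
        np.testing.assert_allclose(
            bk.adjust_pvalues([0.01, 0.02, 0.03], "BH"), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bk.adjust_pvalues([0.5], "BH"), [0.5])
        np.testing.assert_allclose(bk.adjust_pvalues([0.5], "bonferroni"), [0.5])

    def test_bonferroni_multiplies(self):
        np.testing.assert_allclose(
            bk.adjust_pvalues([0.04] * 5, "bonferroni"), [0.2] * 5)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bonferroni_dominates_bh_and_order_preserved(self, ps):
        bh = bk.adjust_pvalues(ps, "BH")
        bf = bk.adjust_pvalues(ps, "bonferroni")
        assert (bf >= bh - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(bh[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bk.adjust_pvalues([0.1, 1.5], "BH")


def test_compare_all_table(labeled_cohort):
    table = bk.compare_all(labeled_cohort, ["plasma_ptau217", "plasma_ptau181",
                                            "plasma_nfl"])
    assert len(table) == 3
    assert set(table["test_used"]) <= {"t", "wilcoxon"}
    assert (table["p_bonferroni"] >= table["p_fdr"] - 1e-12).all()
    row = table.set_index("variable").loc["plasma_ptau217"]
    assert row["d"] > 1.0 and row["p_adjusted_age_sex"] < 0.001
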