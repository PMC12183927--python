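"""ROC machinery against exhaustive oracles and external references."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import bbadkit as bk

from conftest import SEED


def pair_count_auc(pos, neg):
    """Exhaustive Mann-Whitney oracle: all pos x neg pairs, ties half."""
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(pos, neg):
    """Best J over every observed threshold with predicate x >= t."""
    best = -np.inf
    for t in np.unique(np.concatenate([pos, neg])):
        se = np.mean(pos >= t)
        sp = np.mean(neg < t)
        best = max(best, se + sp - 1.0)
    return best


def _scores_labels(pos, neg):
    return (np.concatenate([pos, neg]),
            np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)]))


class TestAUC:
    @pytest.mark.parametrize("pos,neg,expected", [
        ([3, 4, 5], [1, 2], 1.0),            # perfect separation
        ([2, 3, 5], [1, 3, 4], 5.5 / 9),     # mixed with one tie
        ([1, 2], [1, 2], 0.5),               # exchangeable ties
    ])
    def test_hand_counted_examples(self, pos, neg, expected):
        s, y = _scores_labels(np.array(pos, float), np.array(neg, float))
        assert bk.auc_mann_whitney(s, y).auc == pytest.approx(expected)

    def test_matches_sklearn_on_continuous_data(self):
        rng = np.random.default_rng(SEED)
        s = rng.normal(size=200)
        y = (rng.random(200) < 0.4).astype(int)
        y[:2] = [0, 1]  # both classes guaranteed
        ours = bk.auc_mann_whitney(s, y).auc
        assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_flip_symmetry(self):
        rng = np.random.default_rng(SEED)
        s = rng.integers(0, 10, 60).astype(float)
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        a = bk.auc_mann_whitney(s, y).auc
        b = bk.auc_mann_whitney(-s, y).auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bk.auc_mann_whitney([1.0, 2.0], [1, 1])

    def test_variance_needs_two_per_class(self):
        with pytest.raises(ValueError):
            bk.auc_mann_whitney([1.0, 2.0, 3.0], [1, 0, 0])


class TestOrientation:
    def test_higher_in_positives(self, labeled_cohort):
        y = labeled_cohort.df["a_positive"].to_numpy()
        _, o = bk.orient_scores(labeled_cohort.df["plasma_ptau217"], y)
        assert o == "higher_is_positive"

    def test_lower_in_positives(self, labeled_cohort):
        y = labeled_cohort.df["a_positive"].to_numpy()
        _, o = bk.orient_scores(labeled_cohort.df["plasma_ab42"], y)
        assert o == "lower_is_positive"

    def test_exact_coin_flip_defaults_higher(self):
        s, y = _scores_labels(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        _, o = bk.orient_scores(s, y)
        assert o == "higher_is_positive"


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.data())
def test_auc_and_youden_equal_bruteforce(data):
    """Exact agreement with exhaustive pair counting and threshold sweeps."""
    m = data.draw(st.integers(1, 25))
    n = data.draw(st.integers(1, 25))
    # small integer support forces plenty of ties
    pos = np.array(data.draw(st.lists(st.integers(0, 8), min_size=m, max_size=m)),
                   dtype=float)
    neg = np.array(data.draw(st.lists(st.integers(0, 8), min_size=n, max_size=n)),
                   dtype=float)
    s, y = _scores_labels(pos, neg)
    assert bk.auc_mann_whitney(s, y, variance=False).auc == \
        pytest.approx(pair_count_auc(pos, neg), abs=1e-12)
    if len(np.unique(s)) > 1:
        curve = bk.roc_curve(s, y, orientation="higher_is_positive")
        rep = bk.youden_cutoff(curve)
        assert rep.youden_j == pytest.approx(brute_force_youden(pos, neg),
                                             abs=1e-12)


class TestCurveInvariants:
    def test_sensitivity_monotone_and_endpoints(self, labeled_cohort):
        y = labeled_cohort.df["a_positive"].to_numpy()
        curve = bk.roc_curve(labeled_cohort.df["plasma_ptau181"].to_numpy(), y)
        assert (np.diff(curve.sensitivity) <= 1e-12).all()
        assert curve.sensitivity[0] == 1.0      # loosest threshold
        assert curve.specificity[-1] == 1.0     # +inf sentinel

    def test_rank_invariance_under_monotone_transform(self, labeled_cohort):
        y = labeled_cohort.df["a_positive"].to_numpy()
        s = labeled_cohort.df["plasma_ptau217"].to_numpy()
        a = bk.roc_curve(s, y)
        b = bk.roc_curve(np.log(s), y)
        ra, rb = bk.youden_cutoff(a), bk.youden_cutoff(b)
        assert ra.youden_j == pytest.approx(rb.youden_j, abs=1e-12)
        assert ra.sensitivity == rb.sensitivity
        assert rb.cutoff == pytest.approx(np.log(ra.cutoff))
        assert bk.auc_mann_whitney(s, y).auc == \
            pytest.approx(bk.auc_mann_whitney(np.log(s), y).auc, abs=1e-12)

    def test_youden_tie_break_toward_specificity(self):
        # J = 0.5 both at t=2 (SE=1, SP=.5) and t=4 (SE=.5, SP=1)
        s, y = _scores_labels(np.array([2.0, 4.0]), np.array([1.0, 3.0]))
        rep = bk.youden_cutoff(bk.roc_curve(s, y, orientation="higher_is_positive"))
        assert rep.cutoff == 4.0 and rep.specificity == 1.0


class TestPredictiveValues:
    @pytest.mark.parametrize("se,sp,prev,ppv", [
        (0.836, 0.939, 69 / 102, 0.97),   # plasma pTau217 operating point
        (0.791, 0.818, 69 / 102, 0.90),   # plasma pTau181 operating point
        (0.866, 0.667, 69 / 102, 0.84),   # CSF Abeta42 operating point
    ])
    def test_published_operating_points(self, se, sp, prev, ppv):
        got_ppv, _ = bk.predictive_values(se, sp, prev)
        assert round(got_ppv, 2) == ppv

    def test_perfect_test(self):
        assert bk.predictive_values(1.0, 1.0, 0.3) == (1.0, 1.0)

    def test_degenerate_denominator_flagged_nan(self):
        # SE=0, SP=1 at prevalence 1: nothing is ever called positive
        ppv, npv = bk.predictive_values(0.0, 1.0, 1.0)
        assert np.isnan(ppv)      # no positive calls: PPV undefined
        assert npv == 0.0         # every negative call is wrong
        ppv, npv = bk.predictive_values(1.0, 0.0, 0.0)
        assert np.isnan(npv)      # no negative calls: NPV undefined

    def test_count_conservation(self):
        # TP+FP+TN+FN must equal N at any prevalence
        se, sp, pi, n = 0.8, 0.9, 0.4, 1000
        tp = se * pi * n
        fn = (1 - se) * pi * n
        tn = sp * (1 - pi) * n
        fp = (1 - sp) * (1 - pi) * n
        ppv, npv = bk.predictive_values(se, sp, pi)
        assert tp + fp + tn + fn == pytest.approx(n)
        assert ppv == pytest.approx(tp / (tp + fp))
        assert npv == pytest.approx(tn / (tn + fn))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bk.predictive_values(1.2, 0.5, 0.5)


class TestTwoCutoffs:
    def test_perfect_separation_coincide(self):
        s, y = _scores_labels(np.array([5.0, 6.0, 7.0]), np.array([1.0, 2.0]))
        rep = bk.two_cutoffs(bk.roc_curve(s, y))
        assert rep.rule_in.cutoff == rep.rule_out.cutoff == 5.0
        assert rep.intermediate_fraction == 0.0

    def test_rule_in_exceeds_all_negatives(self):
        pos = np.array([2.0, 3.0, 5.0, 7.0])
        neg = np.array([1.0, 2.0, 3.0, 4.0])
        s, y = _scores_labels(pos, neg)
        rep = bk.two_cutoffs(bk.roc_curve(s, y, orientation="higher_is_positive"))
        # SP >= 0.95 with 4 negatives requires SP = 1 -> threshold above 4
        assert rep.rule_in.cutoff > 4.0
        assert rep.rule_in.specificity == 1.0
        assert rep.rule_out.cutoff <= rep.rule_in.cutoff

    def test_rule_out_reaches_sensitivity_target(self, labeled_cohort):
        y = labeled_cohort.df["a_positive"].to_numpy()
        curve = bk.roc_curve(labeled_cohort.df["plasma_ptau217"].to_numpy(), y)
        rep = bk.two_cutoffs(curve)
        assert rep.rule_out.sensitivity >= 0.95
        assert rep.rule_in.specificity >= 0.95
        assert 0.0 <= rep.intermediate_fraction < 1.0

    def test_unattainable_target_flagged_missing(self):
        # all scores identical: no observed threshold reaches SP >= 0.95
        s = np.ones(20)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        rep = bk.two_cutoffs(bk.roc_curve(s, y, orientation="higher_is_positive"))
        assert rep.rule_in is None

    def test_bad_targets_rejected(self, labeled_cohort):
        y = labeled_cohort.df["a_positive"].to_numpy()
        curve = bk.roc_curve(labeled_cohort.df["plasma_ptau217"].to_numpy(), y)
        with pytest.raises(ValueError):
            bk.two_cutoffs(curve, sens_target=0.4)


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(SEED)
        s = rng.normal(size=50)
        y = np.r_[np.ones(25, int), np.zeros(25, int)]
        cmp_ = bk.delong_paired_test(s, s, y)
        assert cmp_.p == 1.0 and cmp_.degenerate

    def test_monotone_transform_p_one(self):
        rng = np.random.default_rng(SEED)
        s = rng.lognormal(size=60)
        y = (rng.random(60) < 0.5).astype(int)
        y[:2] = [0, 1]
        cmp_ = bk.delong_paired_test(s, np.log(s), y)
        assert cmp_.auc_a == pytest.approx(cmp_.auc_b)
        assert cmp_.p == 1.0

    def test_swap_negates_z_keeps_p(self, labeled_cohort):
        y = labeled_cohort.df["a_positive"].to_numpy()
        a = labeled_cohort.df["plasma_ptau217"].to_numpy()
        b = labeled_cohort.df["plasma_ptau181"].to_numpy()
        ab = bk.delong_paired_test(a, b, y)
        ba = bk.delong_paired_test(b, a, y)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p == pytest.approx(ba.p)

    def test_delong_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(SEED)
        pos = rng.normal(1.0, 1.0, 50)
        neg = rng.normal(0.0, 1.0, 50)
        s, y = _scores_labels(pos, neg)
        res = bk.auc_mann_whitney(s, y)
        boot = np.empty(2000)
        for b in range(2000):
            bp = rng.choice(pos, 50)
            bn = rng.choice(neg, 50)
            boot[b] = bk.auc_mann_whitney(*_scores_labels(bp, bn),
                                          variance=False).auc
        assert res.se_delong ** 2 == pytest.approx(boot.var(ddof=1), rel=0.25)

    def test_paired_p_close_to_bootstrap_difference_test(self):
        rng = np.random.default_rng(SEED)
        n = 20
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        base = rng.normal(y * 1.0, 1.0)
        a = base + rng.normal(0, 0.6, n)
        b = base + rng.normal(0, 0.6, n)
        cmp_ = bk.delong_paired_test(a, b, y)
        diffs = np.empty(10_000)
        for r in range(10_000):
            idx = np.r_[rng.choice(np.where(y == 1)[0], n // 2),
                        rng.choice(np.where(y == 0)[0], n // 2)]
            diffs[r] = (bk.auc_mann_whitney(a[idx], y, variance=False).auc
                        - bk.auc_mann_whitney(b[idx], y, variance=False).auc)
        observed = cmp_.auc_a - cmp_.auc_b
        p_boot = 2 * min((diffs - diffs.mean() >= observed).mean(),
                         (diffs - diffs.mean() <= observed).mean())
        assert cmp_.p == pytest.approx(min(p_boot, 1.0), abs=0.02)


class TestComparisonMatrix:
    def test_combinatorics_and_symmetry(self, labeled_cohort):
        markers = ["plasma_ab42", "plasma_ab40", "plasma_ab42_40",
                   "plasma_ptau181", "plasma_ptau217", "plasma_nfl"]
        mat, comparisons = bk.auc_comparison_matrix(labeled_cohort, markers)
        assert len(comparisons) == 15
        assert np.isnan(np.diag(mat.to_numpy())).all()
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_identical_biomarkers_not_significant(self, labeled_cohort):
        cohort = bk.CohortTable(
            labeled_cohort.df.assign(
                plasma_ptau217_copy=labeled_cohort.df["plasma_ptau217"]))
        mat, comparisons = bk.auc_comparison_matrix(
            cohort, ["plasma_ptau217", "plasma_ptau217_copy"])
        assert comparisons[0].p == 1.0
        assert comparisons[0].fdr_significant is False

    def test_large_sample_pattern_matches_study(self):
        cfg = bk.default_config()
        cfg.n_neg = cfg.n_pos = 1500
        lab = bk.label_cohort(bk.generate_cohort(cfg, seed=SEED))
        mat, comparisons = bk.auc_comparison_matrix(
            lab, ["plasma_ptau217", "plasma_ptau181", "plasma_nfl"])
        by_pair = {(c.biomarker_a, c.biomarker_b): c for c in comparisons}
        assert by_pair[("plasma_ptau217", "plasma_nfl")].fdr_significant
        assert by_pair[("plasma_ptau181", "plasma_nfl")].fdr_significant
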