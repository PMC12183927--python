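"""ROC machinery for diagnostic biomarker evaluation, built from first principles.

Empirical ROC curves with thresholds at observed values, Mann-Whitney AUC
(half credit for ties) with DeLong structural-component variance and
covariance (midrank formulation), Youden-index and dual 95%-sensitivity /
95%-specificity cut-off selection, prevalence-dependent predictive values,
and paired DeLong tests with Benjamini-Hochberg control across all biomarker
pairs.

Orientation convention: scores are oriented so that higher values indicate
the positive (amyloid-abnormal) class before any curve is built, and the
chosen orientation is propagated so cut-offs are reported on the original
measurement scale.  After orientation the positivity predicate is
``score >= threshold``: a value exactly at a cut-off is called positive,
matching the boundary-abnormal convention of the reference standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, special

from .cohort import CohortTable
from .compare import adjust_pvalues

__all__ = [
    "ROCCurve",
    "AUCResult",
    "CutoffReport",
    "TwoCutoffReport",
    "DeLongComparison",
    "orient_scores",
    "auc_mann_whitney",
    "roc_curve",
    "youden_cutoff",
    "predictive_values",
    "two_cutoffs",
    "delong_paired_test",
    "auc_comparison_matrix",
]


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    labels = labels.astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both classes must be present")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return scores, labels


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and DeLong structural components via midranks.

    V10[i] for positive i is the fraction of negatives it beats (ties count
    half); V01[j] for negative j is the fraction of positives beating it.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    # rank-sum form: the numerator is an exact half-integer, so the AUC is
    # bit-identical to exhaustive pair counting
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return float(auc), v10, v01


@dataclass(frozen=True)
class AUCResult:
    auc: float
    se_delong: float
    ci95_low: float
    ci95_high: float
    n_pos: int
    n_neg: int


def auc_mann_whitney(scores, labels, variance: bool = True) -> AUCResult:
    """Empirical AUC (probability a positive outranks a negative, ties half).

    The DeLong standard error and a Wald 95% CI (clipped to [0, 1]) are
    attached when ``variance`` is requested, which needs at least two
    subjects per class.  Scores are used as given — orient first if a
    marker is lower in the positive class.
    """
    scores, labels = _check_scores_labels(scores, labels)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    if not variance:
        return AUCResult(auc, float("nan"), float("nan"), float("nan"), m, n)
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs >= 2 subjects per class")
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    se = float(np.sqrt(max(var, 0.0)))
    return AUCResult(auc=auc, se_delong=se,
                     ci95_low=float(np.clip(auc - 1.96 * se, 0.0, 1.0)),
                     ci95_high=float(np.clip(auc + 1.96 * se, 0.0, 1.0)),
                     n_pos=m, n_neg=n)


def orient_scores(scores, labels) -> tuple[np.ndarray, str]:
    """Orient scores so the Mann-Whitney AUC is >= 0.5.

    Returns (oriented scores, orientation) with orientation
    "higher_is_positive" (scores unchanged) or "lower_is_positive" (scores
    negated).  An AUC of exactly 0.5 defaults to "higher_is_positive".
    """
    scores, labels = _check_scores_labels(scores, labels)
    auc, _, _ = _delong_components(scores, labels)
    if auc < 0.5:
        return -scores, "lower_is_positive"
    return scores.copy(), "higher_is_positive"


@dataclass(frozen=True)
class ROCCurve:
    """Empirical operating points at every observed threshold.

    ``thresholds`` are on the *oriented* scale, ascending, with a final
    +inf sentinel so the (SE=0, SP=1) endpoint is always present; the first
    threshold (the observed minimum) gives (SE=1, SP>=0).  Positivity is
    ``oriented score >= threshold``.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    orientation: str
    n_pos: int
    n_neg: int
    scores_oriented: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    @property
    def prevalence(self) -> float:
        return self.n_pos / (self.n_pos + self.n_neg)

    def original_threshold(self, oriented_threshold: float) -> float:
        """Map an oriented threshold back to the measurement scale."""
        if self.orientation == "lower_is_positive":
            return -oriented_threshold
        return oriented_threshold


def roc_curve(scores, labels, orientation: str | None = None) -> ROCCurve:
    """Build the empirical ROC curve, auto-orienting unless told otherwise."""
    scores, labels = _check_scores_labels(scores, labels)
    if orientation is None:
        oriented, orientation = orient_scores(scores, labels)
    elif orientation == "higher_is_positive":
        oriented = scores.copy()
    elif orientation == "lower_is_positive":
        oriented = -scores
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    pos = np.sort(oriented[labels == 1])
    neg = np.sort(oriented[labels == 0])
    thr = np.unique(oriented)
    thr = np.append(thr, np.inf)
    # predicate score >= t: sensitivity = P_pos(x >= t), specificity = P_neg(x < t)
    sens = 1.0 - np.searchsorted(pos, thr, side="left") / len(pos)
    spec = np.searchsorted(neg, thr, side="left") / len(neg)
    return ROCCurve(thresholds=thr, sensitivity=sens, specificity=spec,
                    orientation=orientation, n_pos=len(pos), n_neg=len(neg),
                    scores_oriented=oriented, labels=labels)


def predictive_values(sensitivity: float, specificity: float,
                      prevalence: float) -> tuple[float, float]:
    """PPV and NPV from sensitivity, specificity and prevalence (Bayes).

    Undefined values (zero denominator) are returned as NaN rather than
    raising, so degenerate operating points stay representable.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    se, sp, pi = sensitivity, specificity, prevalence
    ppv_den = se * pi + (1 - sp) * (1 - pi)
    npv_den = sp * (1 - pi) + (1 - se) * pi
    ppv = se * pi / ppv_den if ppv_den > 0 else float("nan")
    npv = sp * (1 - pi) / npv_den if npv_den > 0 else float("nan")
    return ppv, npv


@dataclass(frozen=True)
class CutoffReport:
    cutoff: float                 # original measurement scale
    orientation: str
    sensitivity: float
    specificity: float
    youden_j: float
    ppv: float
    npv: float
    prevalence: float


def _report_at(curve: ROCCurve, idx: int, prevalence: float) -> CutoffReport:
    se = float(curve.sensitivity[idx])
    sp = float(curve.specificity[idx])
    ppv, npv = predictive_values(se, sp, prevalence)
    return CutoffReport(
        cutoff=float(curve.original_threshold(curve.thresholds[idx])),
        orientation=curve.orientation, sensitivity=se, specificity=sp,
        youden_j=se + sp - 1.0, ppv=ppv, npv=npv, prevalence=prevalence)


def youden_cutoff(curve: ROCCurve, prevalence: float | None = None) -> CutoffReport:
    """Threshold maximizing Youden's J = SE + SP - 1.

    Ties are broken toward the more specific operating point (the clinical
    framing here is confirmatory rule-in).  Predictive values use the
    sample prevalence unless overridden.
    """
    if prevalence is None:
        prevalence = curve.prevalence
    j = curve.sensitivity + curve.specificity - 1.0
    best = j.max()
    # ties -> highest specificity -> largest oriented threshold
    idx = int(np.where(j >= best - 1e-12)[0][-1])
    return _report_at(curve, idx, prevalence)


@dataclass(frozen=True)
class TwoCutoffReport:
    rule_in: CutoffReport | None      # achieves specificity >= spec_target
    rule_out: CutoffReport | None     # achieves sensitivity >= sens_target
    sens_target: float
    spec_target: float
    intermediate_fraction: float


def two_cutoffs(curve: ROCCurve, sens_target: float = 0.95,
                spec_target: float = 0.95,
                prevalence: float | None = None) -> TwoCutoffReport:
    """Dual-threshold rule-in / rule-out report.

    Rule-in: the least extreme observed threshold whose empirical
    specificity reaches ``spec_target``.  Rule-out: the least extreme
    threshold whose sensitivity reaches ``sens_target``.  Subjects whose
    oriented score falls between the two cut-offs form the intermediate
    zone.  An unattainable target yields a missing cut-off, not an error.
    """
    if not (0.5 < sens_target < 1.0) or not (0.5 < spec_target < 1.0):
        raise ValueError("targets must lie in (0.5, 1)")
    if prevalence is None:
        prevalence = curve.prevalence
    observed = slice(0, len(curve.thresholds) - 1)  # exclude +inf sentinel
    spec_ok = np.where(curve.specificity[observed] >= spec_target)[0]
    sens_ok = np.where(curve.sensitivity[observed] >= sens_target)[0]
    rule_in = _report_at(curve, int(spec_ok[0]), prevalence) if len(spec_ok) else None
    rule_out = _report_at(curve, int(sens_ok[-1]), prevalence) if len(sens_ok) else None
    inter = 0.0
    if rule_in is not None and rule_out is not None:
        t_in = curve.thresholds[int(spec_ok[0])]
        t_out = curve.thresholds[int(sens_ok[-1])]
        if t_out < t_in:
            x = curve.scores_oriented
            inter = float(np.mean((x >= t_out) & (x < t_in)))
    return TwoCutoffReport(rule_in=rule_in, rule_out=rule_out,
                           sens_target=sens_target, spec_target=spec_target,
                           intermediate_fraction=inter)


@dataclass(frozen=True)
class DeLongComparison:
    biomarker_a: str
    biomarker_b: str
    auc_a: float
    auc_b: float
    z: float
    p: float
    degenerate: bool = False
    fdr_significant: bool | None = None


def delong_paired_test(scores_a, scores_b, labels,
                       name_a: str = "a", name_b: str = "b") -> DeLongComparison:
    """Paired DeLong test for two correlated AUCs on the same subjects.

    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov_ab) with variances and
    covariance from the structural components; two-sided normal p value.
    A zero-variance difference is flagged degenerate (p = 1 when the AUCs
    are equal, which includes any strictly monotone transform of the same
    scores).
    """
    scores_a, labels = _check_scores_labels(scores_a, labels)
    scores_b, labels_b = _check_scores_labels(scores_b, labels)
    auc_a, v10a, v01a = _delong_components(scores_a, labels)
    auc_b, v10b, v01b = _delong_components(scores_b, labels)
    m, n = len(v10a), len(v01a)
    if m < 2 or n < 2:
        raise ValueError("paired DeLong test needs >= 2 subjects per class")
    s10 = np.cov(v10a, v10b, ddof=1)
    s01 = np.cov(v01a, v01b, ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var_diff <= 1e-300:
        equal = abs(auc_a - auc_b) < 1e-12
        return DeLongComparison(name_a, name_b, auc_a, auc_b,
                                z=0.0 if equal else np.inf,
                                p=1.0 if equal else 0.0, degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * special.ndtr(-abs(z))
    return DeLongComparison(name_a, name_b, auc_a, auc_b,
                            z=float(z), p=float(p))


def auc_comparison_matrix(cohort: CohortTable, biomarkers: list[str],
                          alpha: float = 0.05):
    """All-pairs DeLong comparisons with Benjamini-Hochberg control.

    Each biomarker is oriented on its own (so all AUCs are >= 0.5) before
    the paired tests.  Returns ``(p_matrix, comparisons)``: a symmetric
    DataFrame of p values (NaN diagonal) and the list of
    :class:`DeLongComparison` for the unordered pairs, with FDR flags set
    over exactly that family of tests.
    """
    if len(biomarkers) < 2:
        raise ValueError("need at least 2 biomarkers to compare")
    df = cohort.df
    if "a_positive" not in df.columns:
        raise ValueError("cohort is not labeled; call label_cohort first")
    labels = df["a_positive"].to_numpy()
    oriented = {b: orient_scores(df[b].to_numpy(dtype=float), labels)[0]
                for b in biomarkers}
    comparisons: list[DeLongComparison] = []
    for i, a in enumerate(biomarkers):
        for b in biomarkers[i + 1:]:
            comparisons.append(
                delong_paired_test(oriented[a], oriented[b], labels, a, b))
    p_adj = adjust_pvalues([c.p for c in comparisons], "BH")
    comparisons = [
        DeLongComparison(c.biomarker_a, c.biomarker_b, c.auc_a, c.auc_b,
                         c.z, c.p, c.degenerate, bool(q < alpha))
        for c, q in zip(comparisons, p_adj)
    ]
    mat = pd.DataFrame(np.nan, index=biomarkers, columns=biomarkers)
    for c in comparisons:
        mat.loc[c.biomarker_a, c.biomarker_b] = c.p
        mat.loc[c.biomarker_b, c.biomarker_a] = c.p
    return mat, comparisons
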