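"""Two-group biomarker comparisons between amyloid-negative and -positive subjects.

Implements the descriptive-table machinery of the analysis: Shapiro-Wilk
normality routing between Welch's t-test and the Wilcoxon rank-sum test,
chi-square tests for categoricals, percent median difference, pooled-SD
Cohen's d with a normal-approximation confidence interval, age/sex-adjusted
group p values via ANCOVA, and Benjamini-Hochberg / Bonferroni multiplicity
control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable, split_groups

__all__ = [
    "EffectSize",
    "GroupComparison",
    "cohen_d",
    "compare_groups",
    "ancova_adjusted_p",
    "adjust_pvalues",
    "chi_square_categorical",
    "compare_all",
]

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class EffectSize:
    """Standardized mean difference, positive group minus negative group."""

    d: float
    se: float
    ci95_low: float
    ci95_high: float


@dataclass(frozen=True)
class GroupComparison:
    biomarker: str
    test_used: str               # "t" | "wilcoxon"
    p_raw: float
    p_adjusted_age_sex: float
    percent_median_diff: float
    effect: EffectSize
    shapiro_p_neg: float
    shapiro_p_pos: float
    n_neg: int
    n_pos: int


def cohen_d(mean_neg: float, sd_neg: float, n_neg: int,
            mean_pos: float, sd_pos: float, n_pos: int) -> EffectSize:
    """Pooled-SD Cohen's d with normal-approximation 95% CI.

    d = (mean_pos - mean_neg) / s_p with
    s_p^2 = ((n_neg-1) sd_neg^2 + (n_pos-1) sd_pos^2) / (n_neg + n_pos - 2),
    se(d) = sqrt((n_neg+n_pos)/(n_neg n_pos) + d^2 / (2 (n_neg+n_pos))).
    """
    if n_neg < 2 or n_pos < 2:
        raise ValueError("need n >= 2 in each group")
    if sd_neg < 0 or sd_pos < 0:
        raise ValueError("sds must be nonnegative")
    pooled_var = (((n_neg - 1) * sd_neg ** 2 + (n_pos - 1) * sd_pos ** 2)
                  / (n_neg + n_pos - 2))
    if pooled_var <= 0:
        raise ValueError("degenerate pooled SD (both groups constant)")
    d = (mean_pos - mean_neg) / np.sqrt(pooled_var)
    ntot = n_neg + n_pos
    se = np.sqrt(ntot / (n_neg * n_pos) + d ** 2 / (2 * ntot))
    return EffectSize(d=float(d), se=float(se),
                      ci95_low=float(d - 1.96 * se),
                      ci95_high=float(d + 1.96 * se))


def compare_groups(cohort: CohortTable, biomarker: str,
                   alpha: float = SHAPIRO_ALPHA) -> GroupComparison:
    """Compare one biomarker between A- and A+ in a labeled cohort.

    Shapiro-Wilk is run on each group at ``alpha``; the two-sample t-test
    (Welch) is used only if both groups look normal, otherwise the Wilcoxon
    rank-sum (Mann-Whitney) test.  Effect size is pooled-SD Cohen's d from
    the group summary statistics; the adjusted p comes from an age/sex
    ANCOVA.
    """
    neg, pos = split_groups(cohort, biomarker)
    if len(neg) < 3 or len(pos) < 3:
        raise ValueError(
            f"{biomarker}: need >= 3 subjects per group "
            f"(got {len(neg)} / {len(pos)})")
    sw_neg = stats.shapiro(neg).pvalue
    sw_pos = stats.shapiro(pos).pvalue
    if sw_neg > alpha and sw_pos > alpha:
        test_used = "t"
        p_raw = stats.ttest_ind(pos, neg, equal_var=False).pvalue
    else:
        test_used = "wilcoxon"
        p_raw = stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue
    med_neg, med_pos = np.median(neg), np.median(pos)
    pct = 100.0 * (med_pos - med_neg) / med_neg
    eff = cohen_d(neg.mean(), neg.std(ddof=1), len(neg),
                  pos.mean(), pos.std(ddof=1), len(pos))
    p_adj = ancova_adjusted_p(cohort, biomarker)
    return GroupComparison(
        biomarker=biomarker, test_used=test_used, p_raw=float(p_raw),
        p_adjusted_age_sex=float(p_adj), percent_median_diff=float(pct),
        effect=eff, shapiro_p_neg=float(sw_neg), shapiro_p_pos=float(sw_pos),
        n_neg=len(neg), n_pos=len(pos))


def ancova_adjusted_p(cohort: CohortTable, biomarker: str,
                      covariates: tuple[str, ...] = ("age", "sex")) -> float:
    """p value for the group indicator in biomarker ~ group + covariates.

    Least-squares fit with a Wald test on the group coefficient (type-III
    style for the single group term).  Raises on collinear covariates,
    naming the offending columns.
    """
    df = cohort.df
    if "a_positive" not in df.columns:
        raise ValueError("cohort is not labeled; call label_cohort first")
    cols = [biomarker, "a_positive", *covariates]
    sub = df[cols].dropna()
    terms = ["a_positive"] + [
        f"C({c})" if sub[c].dtype == object else c for c in covariates]
    formula = f"{biomarker} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=sub)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify aliased columns from the QR diagonal
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(exog.shape) * np.finfo(float).eps
        aliased = [model.exog_names[j] for j in np.where(diag < tol)[0]]
        raise ValueError(f"collinear covariates in ANCOVA: {aliased}")
    res = model.fit()
    return float(res.pvalues["a_positive"])


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjusted p values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"method must be 'BH' or 'bonferroni', got {method!r}")
    return multipletests(p, method=key)[1]


def chi_square_categorical(cohort: CohortTable, column: str) -> float:
    """Chi-square p value for a categorical column vs amyloid status."""
    df = cohort.df[[column, "a_status"]].dropna()
    table = pd.crosstab(df[column], df["a_status"])
    if min(table.shape) < 2:
        return float("nan")   # single stratum: no contrast to test
    return float(stats.chi2_contingency(table).pvalue)


def compare_all(cohort: CohortTable, biomarkers: list[str],
                alpha_flag: float = 0.05) -> pd.DataFrame:
    """Descriptive comparison table across biomarkers with multiplicity flags.

    One row per biomarker: group means/SDs, percent median difference,
    Cohen's d with CI, raw and age/sex-adjusted p, and significance flags
    for the adjusted p after Benjamini-Hochberg and Bonferroni correction
    over this family of biomarkers.
    """
    rows = []
    for b in biomarkers:
        neg, pos = split_groups(cohort, b)
        cmp_ = compare_groups(cohort, b)
        rows.append({
            "variable": b,
            "mean_neg": neg.mean(), "sd_neg": neg.std(ddof=1),
            "mean_pos": pos.mean(), "sd_pos": pos.std(ddof=1),
            "pct_median_diff": cmp_.percent_median_diff,
            "d": cmp_.effect.d,
            "d_ci_low": cmp_.effect.ci95_low, "d_ci_high": cmp_.effect.ci95_high,
            "test_used": cmp_.test_used,
            "p_raw": cmp_.p_raw,
            "p_adjusted_age_sex": cmp_.p_adjusted_age_sex,
        })
    out = pd.DataFrame(rows)
    out["p_fdr"] = adjust_pvalues(out["p_adjusted_age_sex"], "BH")
    out["p_bonferroni"] = adjust_pvalues(out["p_adjusted_age_sex"], "bonferroni")
    out["fdr_significant"] = out["p_fdr"] < alpha_flag
    out["bonferroni_significant"] = out["p_bonferroni"] < alpha_flag
    return out
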