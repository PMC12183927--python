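"""Per-biomarker regression models.

Logistic models of amyloid status on one standardized biomarker (maximum
likelihood by iteratively reweighted least squares), with an optional
one-pass +/-3 SD outlier-exclusion refit, and linear models of baseline
MMSE on one plasma biomarker plus age, sex, ApoE status, diagnosis and the
biomarker-by-diagnosis interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
import statsmodels.formula.api as smf

from .cohort import CohortTable

__all__ = [
    "LogisticResult",
    "LinearModelResult",
    "logistic_biomarker_model",
    "mmse_linear_model",
]

IRLS_TOL = 1e-10
IRLS_MAX_ITER = 100


@dataclass(frozen=True)
class LogisticResult:
    biomarker: str
    standardized_coefficient: float   # log-odds per SD of the predictor
    se: float
    p: float
    intercept: float
    n_used: int
    outliers_excluded: int
    exclusion_rule: str | None
    separation: bool
    n_iter: int


def _irls_logistic(x: np.ndarray, y: np.ndarray,
                   tol: float = IRLS_TOL,
                   max_iter: int = IRLS_MAX_ITER):
    """Two-parameter logistic ML fit (intercept + slope) by IRLS.

    Returns (beta, cov, n_iter, separated).  Separation is flagged when the
    coefficient diverges (perfectly or quasi-perfectly separated data); the
    caller reports a signed infinite sentinel instead of crashing.
    """
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    separated = False
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -35.0, 35.0)
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            separated = True
            break
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.abs(beta[1]) > 25.0:
            separated = True
            break
        if step < tol:
            break
    else:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last step {step:.3e}, beta {beta})")
    eta = np.clip(X @ beta, -35.0, 35.0)
    mu = special.expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov, it, separated


def logistic_biomarker_model(cohort: CohortTable, biomarker: str,
                             exclude_outliers: bool = False) -> LogisticResult:
    """Logistic fit of amyloid status on one z-scored biomarker.

    The predictor is standardized (z-score) on the analysis sample, so the
    coefficient is a log-odds change per predictor SD and magnitudes are
    comparable across biomarkers.  With ``exclude_outliers``, values beyond
    mean +/- 3 SD (computed once on the full sample) are dropped before
    standardization and refitting.
    """
    df = cohort.df
    if "a_positive" not in df.columns:
        raise ValueError("cohort is not labeled; call label_cohort first")
    sub = df[[biomarker, "a_positive"]].dropna()
    x = sub[biomarker].to_numpy(dtype=float)
    y = sub["a_positive"].to_numpy(dtype=float)
    n_total = len(x)
    n_out = 0
    rule = None
    if exclude_outliers:
        mu, sd = x.mean(), x.std(ddof=1)
        keep = np.abs(x - mu) <= 3.0 * sd
        n_out = int((~keep).sum())
        rule = "mean +/- 3 SD (full sample, one pass)"
        x, y = x[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required after exclusions")
    sd_x = x.std(ddof=1)
    if sd_x == 0:
        raise ValueError(f"{biomarker}: constant predictor")
    z = (x - x.mean()) / sd_x
    beta, cov, n_iter, separated = _irls_logistic(z, y)
    if separated:
        coef = float(np.sign(beta[1]) * np.inf)
        return LogisticResult(biomarker, coef, float("nan"), float("nan"),
                              float(beta[0]), len(z), n_out, rule,
                              separation=True, n_iter=n_iter)
    se = float(np.sqrt(cov[1, 1]))
    p = 2.0 * special.ndtr(-abs(beta[1] / se))
    return LogisticResult(biomarker, float(beta[1]), se, float(p),
                          float(beta[0]), len(z), n_out, rule,
                          separation=False, n_iter=n_iter)


@dataclass(frozen=True)
class LinearModelResult:
    biomarker: str
    terms: pd.DataFrame      # term, coefficient, se, p (+ ci bounds)
    model_p: float           # overall F-test
    r_squared: float
    n_used: int
    n_excluded: int


def mmse_linear_model(cohort: CohortTable, biomarker: str,
                      include_education: bool = False) -> LinearModelResult:
    """Linear model of MMSE on one biomarker with clinical covariates.

    MMSE ~ biomarker + diagnosis + age + ApoE + sex + biomarker:diagnosis
    (+ education).  Diagnosis reference level is dementia, so the MCI
    indicator measures the higher expected MMSE of MCI subjects.  Subjects
    with missing MMSE or diagnosis are excluded and counted.  Coefficients
    are unstandardized, with two-sided t-test p values per term and the
    overall F-test p.
    """
    df = cohort.df
    cols = ["mmse", "diagnosis", "age", "apoe_e4", "sex", biomarker]
    if include_education:
        cols.append("education")
    sub = df[cols].dropna()
    n_excluded = len(df) - len(sub)
    if len(sub) < len(cols) + 3:
        raise ValueError("too few complete rows to fit the MMSE model")
    rhs = [
        biomarker,
        "C(diagnosis, Treatment(reference='dementia'))",
        "age",
        "C(apoe_e4, Treatment(reference='noncarrier'))",
        "C(sex, Treatment(reference='male'))",
        f"{biomarker}:C(diagnosis, Treatment(reference='dementia'))",
    ]
    if include_education:
        rhs.insert(5, "education")
    model = smf.ols("mmse ~ " + " + ".join(rhs), data=sub)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        _, r = np.linalg.qr(model.exog)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(model.exog.shape) * np.finfo(float).eps
        aliased = [model.exog_names[j] for j in np.where(diag < tol)[0]]
        raise ValueError(f"rank-deficient MMSE model; aliased terms: {aliased}")
    res = model.fit()
    pretty = {
        "Intercept": "intercept",
        biomarker: biomarker,
        "C(diagnosis, Treatment(reference='dementia'))[T.MCI]": "diagnosis[MCI]",
        "age": "age",
        "C(apoe_e4, Treatment(reference='noncarrier'))[T.carrier]": "apoe_e4[carrier]",
        "C(sex, Treatment(reference='male'))[T.female]": "sex[female]",
        f"{biomarker}:C(diagnosis, Treatment(reference='dementia'))[T.MCI]":
            f"{biomarker}:diagnosis[MCI]",
        "education": "education",
    }
    ci = res.conf_int(alpha=0.05)
    terms = pd.DataFrame({
        "term": [pretty.get(name, name) for name in res.params.index],
        "coefficient": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "p": res.pvalues.to_numpy(),
        "ci_low": ci[0].to_numpy(),
        "ci_high": ci[1].to_numpy(),
    })
    return LinearModelResult(
        biomarker=biomarker, terms=terms, model_p=float(res.f_pvalue),
        r_squared=float(res.rsquared), n_used=int(res.nobs),
        n_excluded=n_excluded)
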