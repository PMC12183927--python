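# Methods

This note records the statistical model behind each stage of the pipeline,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical details a maintainer would
need to modify the code safely.

## Reference standard and boundary convention

Amyloid status (the binary label every downstream stage conditions on) is
defined by a CSF measure against a fixed assay cut-off with a declared
*normal* side: CSF Aβ42/40 > 0.069 is normal (A−) by default; the
alternative standard is CSF Aβ42/pTau181 > 8.1. Tau status uses CSF
pTau181 < 56.5 pg/ml as normal. Because the assay's normal ranges are
strict inequalities, a value exactly at a cut-off is classified abnormal;
the same convention is used by the ROC thresholds (positivity is
`score ≥ threshold` after orientation), so the two classification surfaces
agree at boundaries.

Derived ratios (CSF Aβ42/40, Aβ42/tTau, Aβ42/pTau, plasma Aβ42/40) are
always recomputed from the raw concentrations; ratio columns in input files
are ignored to rule out internally inconsistent tables. Subjects missing
any biomarker, age or sex are excluded at ingestion and counted, mirroring
the cohort's inclusion rule; a missing clinical diagnosis is a first-class
category that only excludes a subject from diagnosis-stratified analyses
(the MMSE models and the MCI-only subset), never from amyloid-status
analyses.

## Synthetic cohort generator

The generator emulates a memory-clinic sample of 102 consecutive subjects:
33 A− and 69 A+, with group-specific age (66.9 ± 8.6 vs 73.0 ± 6.1 y),
education, MMSE, sex mix, ApoE ε4 carriage (18 % vs 49 %) and diagnosis mix
(MCI vs dementia, with missing-diagnosis rates of 8/33 and 2/69). All
concentrations are drawn from lognormals whose (μ, σ) are solved in closed
form from the target group mean and SD (σ² = ln(1+(sd/mean)²),
μ = ln mean − σ²/2) — positive support and right skew are what clinical
immunoassay data look like, and matching first and second moments is the
only bridge available when a study publishes means and SDs.

**Label-defining ratio.** The CSF Aβ42/40 ratio must fall on the correct
side of 0.069 for every subject, or the generator would create label noise
in its own reference standard. It is therefore drawn per group from a
one-sided truncated normal (A− on (0.069, ∞), A+ on (0, 0.069]) whose
parent parameters are root-found so that the *truncated* distribution has
exactly the configured mean and SD; sampling goes through the inverse CDF,
which is distribution-equivalent to rejection sampling but exact and
rejection-free. Naive truncation of N(mean, sd²) would bias the group mean
by roughly half a MC standard error at n = 5000, which the moment-recovery
tests would see. The configured group means (0.0933, 0.0446) are the
ratios implied by the published Aβ42 and Aβ40 group means; CSF Aβ42 is then
*derived* as ratio × Aβ40, which reproduces the published Aβ42 group means
by construction while keeping label, ratio and concentrations mutually
consistent (its SD is implied rather than matched — the published
(Aβ42, Aβ40, ratio) SD triplet is not arithmetically consistent at the
printed precision, so something has to give, and we chose the column that
is recomputed from parts anyway).

**Correlation.** Biomarkers share a latent Gaussian factor structure:
z = √ρ_g·g + √(ρ_f − ρ_g)·g_family + √(1 − ρ_f)·ε, giving correlation ρ_f
(default 0.7) within an analyte family (amyloid / tau / neurodegeneration)
and ρ_g (default 0.3) across families, positive semi-definite by
construction. The study published only a correlation heat-map, not a
matrix; these defaults produce the strong plasma-pTau/CSF-pTau association
it shows and are declared assumptions, not published values.

**Outliers.** Plasma Aβ42 and Aβ40 receive multiplicative outliers (each
value independently multiplied or divided by 3 with probability 0.02),
emulating the heavy tails that degrade the plasma ratio in practice. The
pre-outlier lognormal is shrunk by the multiplier's moments
(E[M], E[M²]) so the *post*-outlier mixture matches the configured group
moments in expectation. A rate of 0.05 is infeasible at the A− group's
tight CV (≈ 0.24): the outlier mixture alone would exceed the target
variance, which the generator reports as an error.

**Randomness.** One integer seed governs everything. Every draw for
subject *i* comes from a counter-based substream keyed by (i, purpose),
where *purpose* hashes "demographics", "noise:<biomarker>", etc. — adding a
biomarker to a configuration therefore cannot perturb any other column.

**What the generator does not emulate:** pre-analytical covariates (renal
function, BMI, centrifugation), assay drift, longitudinal change, or the
true (unpublished) distributional shapes and correlations. Tests passing
on synthetic cohorts show the *machinery* is correct under a realistic
data-generating process; they cannot certify performance numbers on real
patients.

## Group comparisons

Shapiro–Wilk at α = 0.05 on each group routes to the two-sample *t*-test
only when both groups look normal, otherwise to the Wilcoxon rank-sum
test. The *t* is Welch's (unequal variances): the groups' SDs differ up to
three-fold, so pooling variances for the test would be indefensible even
though the effect size uses the pooled SD by convention. Cohen's *d* uses
the pooled-SD, n−2 denominator and a normal-approximation CI — this choice
reproduces the published effect sizes for all six reproducible biomarker
rows. The percent median difference is computed on data, not summary
statistics (medians are not recoverable from published means). ANCOVA
adjustment is a least-squares fit of biomarker ~ group + age + sex with a
Wald test on the group coefficient. Multiplicity control offers
Benjamini–Hochberg and Bonferroni; the comparison-table family is the set
of biomarkers in the table, and the DeLong family is the 15 plasma pairs.

## ROC, cut-offs, predictive values

The AUC is the Mann–Whitney statistic with half credit for ties, computed
from the rank-sum (the numerator is an exact half-integer, so the result is
bit-identical to exhaustive pair counting). Scores are oriented before any
curve is built so the AUC is ≥ 0.5 — markers depressed in disease (Aβ42 and
all ratios) are negated internally and cut-offs mapped back to the
measurement scale with a direction annotation. DeLong structural
components V₁₀ (per positive subject) and V₀₁ (per negative) are computed
with midranks; the AUC variance is S₁₀/m + S₀₁/n and paired comparisons use
the analogous covariance. The CI is Wald on the AUC scale, clipped to
[0, 1], which matches the symmetric intervals clinical papers print; a
zero-variance difference (identical or monotone-transformed scores) is
flagged degenerate with p = 1.

Thresholds sit at observed values plus a +∞ sentinel so both trivial
operating points exist. Youden ties break toward specificity because the
clinical use case is confirmatory (rule-in). The two-cutoff report returns
the least extreme observed thresholds reaching 95 % specificity (rule-in)
and 95 % sensitivity (rule-out), the fraction of subjects between them,
and flags an unreachable target as missing rather than erroring (the +∞
sentinel is not eligible). Predictive values default to the analyzed
sample's prevalence and accept an override, since PPV/NPV are
prevalence-dependent and a memory-clinic prevalence (~67 %) is far from a
screening population's.

## Regression models

The logistic stage z-scores the predictor on the analysis sample, so the
coefficient is a log-odds change per predictor SD and magnitudes compare
across markers of wildly different units (standardizing the outcome of a
logistic model is not meaningful). Fitting is IRLS to tolerance 1e-10
(max 100 iterations); quasi-separation is detected by coefficient
divergence and reported as a signed infinite sentinel with a flag instead
of a crash. The optional outlier rule drops values outside mean ± 3 SD,
computed once on the full sample — not iteratively, which would be a
different (and unstated) procedure.

The MMSE model is OLS of MMSE on one marker plus diagnosis, age, ApoE ε4,
sex and the marker × diagnosis interaction (optionally education), with
dementia as the diagnosis reference level so the MCI indicator is the
expected MMSE advantage of MCI subjects. Subjects missing MMSE or
diagnosis are excluded and counted; rank deficiency raises an error naming
the aliased terms.

## Robustness simulation

Measurement noise is multiplicative Gaussian: x → x·(1+e), e ~ N(0, cv²),
because a coefficient of variation is a relative-error concept and
concentrations are positive; values are floored at 1 % of the original to
preserve positivity (at cv = 0.25 the floor engages with probability
< 1e-4 and is negligible). The grid is 0 to 0.25 in steps of 0.025 with
500 replicates per level; orientation is frozen from the unperturbed data
so that extreme noise cannot flip a marker's direction and spuriously hold
the AUC near 0.5 from below. Ratio markers perturb numerator and
denominator independently and recompute the ratio — to first order the
ratio's noise CV is √2 times the per-assay CV, which is precisely why the
plasma Aβ42/40 ratio, whose group separation is small relative to its
spread, degrades much faster than the pTau markers. The verdict classifies
a marker as robust when its mean AUC drop at the maximal CV is at most a
threshold (default 0.05).

One behavior worth knowing: under this multiplicative noise law the AUC
does not decay to 0.5 as cv → ∞. Because the noise scales with the signal,
the groups' relative magnitudes survive arbitrarily large cv and the AUC
approaches a plateau strictly above 0.5 (about Φ(Δ/σ_eff) ≈ 0.56 for a 2:1
separation, higher once the positivity floor engages). Additive noise
would erase discrimination completely; multiplicative noise cannot.

## Problem sizes and numerical details

Unit and property tests run at n ≤ 200 with exhaustive oracles (pair
counting, brute-force threshold sweeps, direct likelihood maximization,
QR/lstsq refits). Calibration checks use 20 × 2000 bootstrap resamples at
n = 100 for the DeLong variance, 200 seeds for CI coverage of the MMSE
model, and n = 5000 per group for generator moment recovery (3 Monte-Carlo
SEs, with the SD's standard error estimated from the sample's fourth
central moment). Robustness curves in tests use 500 replicates on the
102-subject default cohort. The truncated-normal moment matcher solves a
2-parameter least-squares problem from several starting points and raises
if the residual exceeds 1e-9 relative — near the feasibility boundary
(target mean close to the cut-off with a large SD) the family simply
cannot realize the requested moments, and failing loudly beats silently
generating a mismatched cohort.

## Known limitations

- Published operating points, AUCs and regression coefficients from real
  cohorts are not reproducible from summary statistics; the pipeline
  reproduces the *procedures*, and the deterministic formulas reproduce
  exactly the numbers that are functions of published inputs (effect
  sizes, predictive values).
- The copula correlations, outlier settings and lognormal shapes are
  declared assumptions standing in for unpublished data properties.
- PPV/NPV are only as transportable as the prevalence they assume.
- The robustness noise law is a model of pre-analytical variability, not a
  measurement of any particular assay's error structure.
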