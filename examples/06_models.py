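"""Per-biomarker regression models.

Logistic models of amyloid status on each standardized biomarker (log-odds
per predictor SD, so magnitudes are comparable across markers), and a
linear model of baseline MMSE on plasma pTau217 with clinical covariates.
For the MMSE part the generator is configured with a structural dependence
(MMSE = 24 + 2*MCI - 2*pTau217 + noise) so the fit has something to
recover; the default configuration draws MMSE from group moments only.
"""

import bbadkit as bk

labeled = bk.label_cohort(bk.generate_cohort(bk.default_config(), seed=0))

print("logistic models (amyloid status ~ z-scored biomarker):")
for marker in ("plasma_ptau217", "plasma_ptau181", "plasma_ab42_40",
               "plasma_nfl"):
    res = bk.logistic_biomarker_model(labeled, marker)
    print(f"  {marker:16s} st.coef = {res.standardized_coefficient:+.2f}  "
          f"p = {res.p:.4f}")

res = bk.logistic_biomarker_model(labeled, "plasma_ab42_40",
                                  exclude_outliers=True)
print(f"  plasma_ab42_40 excluding {res.outliers_excluded} outliers "
      f"(+/-3 SD): st.coef = {res.standardized_coefficient:+.2f}")

cfg = bk.default_config()
cfg.mmse_model = {"intercept": 24.0, "mci_effect": 2.0,
                  "slopes": {"plasma_ptau217": -2.0}, "sd": 2.0}
structured = bk.label_cohort(bk.generate_cohort(cfg, seed=0))
print("\nMMSE ~ pTau217 + diagnosis + age + ApoE + sex + interaction")
print("(true slope -2, true MCI effect +2):")
lm = bk.mmse_linear_model(structured, "plasma_ptau217")
print(lm.terms[["term", "coefficient", "se", "p"]].round(3).to_string(index=False))
print(f"overall model p = {lm.model_p:.4g} on n = {lm.n_used}")
# A negative pTau217 coefficient means higher plasma pTau goes with worse
# cognition at the same age/diagnosis; the MCI indicator is positive
# because MCI subjects score higher than dementia subjects.
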