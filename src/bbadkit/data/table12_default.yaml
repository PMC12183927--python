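# Default synthetic-cohort configuration: a memory-clinic sample of 102
# consecutive subjects (33 amyloid-negative, 69 amyloid-positive) with
# group-specific demographics and biomarker moments taken from the study's
# published summary tables.  Correlation strengths and outlier settings are
# declared modelling assumptions of this package (the study published only
# group means/SDs), not published quantities.
n_neg: 33
n_pos: 69

demographics:
  age:       {mean_neg: 66.9, sd_neg: 8.6,  mean_pos: 73.0, sd_pos: 6.1}
  education: {mean_neg: 10.4, sd_neg: 3.1,  mean_pos: 9.4,  sd_pos: 4.2}
  mmse:      {mean_neg: 24.2, sd_neg: 4.16, mean_pos: 22.4, sd_pos: 4.21}
  male_fraction:            {neg: 0.364, pos: 0.551}   # 12/33, 38/69
  apoe_e4_carrier_fraction: {neg: 0.182, pos: 0.493}   # 6/33, 34/69
  missing_diagnosis_rate:   {neg: 0.242, pos: 0.029}   # 8/33, 2/69 (10/102 overall)
  mci_fraction_given_known: {neg: 0.360, pos: 0.507}   # 9/25, 34/67

# CSF Abeta42/40 ratio defines the amyloid reference label, so it is drawn
# from a one-sided truncated normal per group (A- strictly above the cut-off,
# A+ at or below), moment-matched after truncation.  Group means are the
# ratios implied by the published Abeta42 and Abeta40 group means
# (966.09/10352.06 and 555.58/12459.38), which round to the printed 0.09/0.05.
amyloid_ratio:
  cutoff: 0.069
  mean_neg: 0.09332
  sd_neg: 0.010
  mean_pos: 0.04459
  sd_pos: 0.010

# Latent Gaussian copula: rho_global across all biomarkers, rho_family within
# an analyte family (amyloid / tau / neurodegeneration).
correlation:
  rho_global: 0.3
  rho_family: 0.7

# All concentrations are moment-matched lognormals per amyloid group.
# csf_ab42 is NOT drawn: it is derived as amyloid_ratio * csf_ab40 so that
# the label is exactly consistent with the recomputed ratio.
biomarkers:
  - {name: csf_ab40,       family: amyloid, mean_neg: 10352.06, sd_neg: 3782.77, mean_pos: 12459.38, sd_pos: 4732.43}
  - {name: csf_ttau,       family: tau,     mean_neg: 335.48,   sd_neg: 139.22,  mean_pos: 643.63,   sd_pos: 294.15}
  - {name: csf_ptau181,    family: tau,     mean_neg: 39.26,    sd_neg: 16.14,   mean_pos: 113.60,   sd_pos: 62.01}
  - {name: plasma_ab42,    family: amyloid, mean_neg: 30.91,    sd_neg: 7.51,    mean_pos: 21.41,    sd_pos: 9.56,
     outlier_rate: 0.02, outlier_scale: 3.0}
  - {name: plasma_ab40,    family: amyloid, mean_neg: 347.99,   sd_neg: 83.24,   mean_pos: 301.99,   sd_pos: 127.55,
     outlier_rate: 0.02, outlier_scale: 3.0}
  - {name: plasma_ptau181, family: tau,     mean_neg: 1.68,     sd_neg: 0.64,    mean_pos: 3.28,     sd_pos: 1.77}
  - {name: plasma_ptau217, family: tau,     mean_neg: 0.18,     sd_neg: 0.11,    mean_pos: 0.83,     sd_pos: 0.56}
  - {name: plasma_nfl,     family: neuro,   mean_neg: 47.73,    sd_neg: 34.24,   mean_pos: 34.78,    sd_pos: 28.84}
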