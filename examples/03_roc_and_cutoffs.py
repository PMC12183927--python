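"""ROC analysis of plasma pTau217: AUC with DeLong CI, Youden cut-off,
predictive values, and the dual rule-in / rule-out cut-off approach."""

import bbadkit as bk

labeled = bk.label_cohort(bk.generate_cohort(bk.default_config(), seed=0))
y = labeled.df["a_positive"].to_numpy()
scores = labeled.df["plasma_ptau217"].to_numpy()

oriented, orientation = bk.orient_scores(scores, y)
auc = bk.auc_mann_whitney(oriented, y)
print(f"AUC = {auc.auc:.3f} [{auc.ci95_low:.3f}, {auc.ci95_high:.3f}] "
      f"({orientation})")

curve = bk.roc_curve(scores, y)
rep = bk.youden_cutoff(curve)
print(f"Youden cut-off = {rep.cutoff:.3f} pg/ml  "
      f"SE={rep.sensitivity:.3f} SP={rep.specificity:.3f} "
      f"PPV={rep.ppv:.2f} NPV={rep.npv:.2f}")

two = bk.two_cutoffs(curve)
print(f"rule-in  (SP>=0.95): {two.rule_in.cutoff:.3f} pg/ml, "
      f"PPV={two.rule_in.ppv:.2f}")
print(f"rule-out (SE>=0.95): {two.rule_out.cutoff:.3f} pg/ml, "
      f"NPV={two.rule_out.npv:.2f}")
print(f"intermediate zone: {100 * two.intermediate_fraction:.1f}% of subjects")
# A value above the rule-in cut-off confirms amyloid pathology with high
# post-test probability; below the rule-out cut-off it is unlikely; the
# intermediate zone would still need CSF or PET.
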