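"""Head-to-head AUC comparisons between plasma biomarkers (paired DeLong
tests on the same subjects, Benjamini-Hochberg over all 15 pairs)."""

import bbadkit as bk

labeled = bk.label_cohort(bk.generate_cohort(bk.default_config(), seed=0))
markers = ["plasma_ab42", "plasma_ab40", "plasma_ab42_40",
           "plasma_ptau181", "plasma_ptau217", "plasma_nfl"]
matrix, comparisons = bk.auc_comparison_matrix(labeled, markers)

print("pairwise DeLong p values:")
print(matrix.round(3).to_string())
print("\nsignificant after FDR control:")
for c in comparisons:
    if c.fdr_significant:
        better = c.biomarker_a if c.auc_a > c.auc_b else c.biomarker_b
        print(f"  {c.biomarker_a} vs {c.biomarker_b}: "
          f"AUC {c.auc_a:.3f} vs {c.auc_b:.3f} (p={c.p:.4f}) -> {better}")
# pTau217 should dominate the weaker markers (Abeta40, NfL) while the
# pTau217 vs pTau181 contrast is typically not significant at n=102.
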