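"""ROC evaluation of a down-regulated circRNA marker.

AUC with a Hanley-McNeil confidence interval and p versus the uninformative
0.5, plus the Youden-optimal cutoff with its sensitivity and specificity.
"""

from circad import default_cohort_config, evaluate_marker, generate_cohort

cohort = generate_cohort(default_cohort_config(seed=17))
is_case = cohort.group == "case"

for marker in ("hsa_circRPRD1A", "hsa_circHERPUD2"):
    res = evaluate_marker(cohort.loc[is_case, marker], cohort.loc[~is_case, marker])
    print(
        f"{marker}: AUC {res.auc:.3f} (95% CI {res.auc_ci[0]:.3f}-{res.auc_ci[1]:.3f}, "
        f"p={res.auc_p:.3f}); direction '{res.direction}'\n"
        f"  Youden cutoff {res.cutoff:.3f}: sensitivity {res.sensitivity:.3f}, "
        f"specificity {res.specificity:.3f}"
    )

# direction 'lower' means low expression indicates disease, as expected for
# markers down-regulated in cases; AUC is oriented to be >= 0.5.
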