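"""Full statistics stage on a simulated 77-patient cohort.

Group comparisons with an adaptive test gate, univariate/multivariate
logistic regression (odds ratios per 1 SD), ROC analysis of each parameter
and of the three composite diffusion-model scores, and DeLong paired AUC
comparisons against the kurtosis composite.
"""
import pandas as pd

from rsikit import generate_cohort_table, run_full_analysis

pd.set_option("display.width", 120)

cohort = generate_cohort_table(n_positive=31, n_negative=46, seed=1)
report = run_full_analysis(cohort)

print("group comparisons (test chosen by the normality gate):")
print(report["table1"][["variable", "test", "p_value"]].round(4).to_string(
    index=False))

print("\nROC of single parameters and composite models:")
cols = ["marker", "auc", "cutoff", "sensitivity", "specificity"]
print(report["table3"][cols].round(3).to_string(index=False))

print("\npaired AUC comparisons vs the kurtosis composite (DeLong):")
print(report["delong"].round(3).to_string(index=False))
# An AUC near 0.5 (f2) carries no discriminative information; values
# above ~0.8 indicate strong separation of the nodal-status groups.
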