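"""Group-comparison statistics for a cohort demographic table.

Reproduces the published multi-site MDD consortium comparison from its
summary table: a Yates continuity-corrected chi-square for the sex split
and Welch t statistics recomputed from the rounded group summaries.
"""

from neurofuse.interpret import (ContingencyTable2x2, chisq_yates,
                                 welch_from_summary)

# sex split: MDD 463 male / 813 female, HC 462 male / 642 female
chi2, p = chisq_yates(ContingencyTable2x2(463, 813, 462, 642))
print(f"sex:       chi2 = {chi2:.4f}, p = {p:.4f}  "
      "(continuity-corrected, df = 1)")

t_age = welch_from_summary(36.23, 14.62, 1276, 36.15, 15.67, 1104)
print(f"age:       Welch t = {t_age:.4f}  (from rounded group summaries)")

t_edu = welch_from_summary(11.25, 4.21, 1276, 12.25, 4.98, 1104)
print(f"education: Welch t = {t_edu:.4f}")

print("\nThe sex imbalance is significant (p < 0.01); education differs "
      "strongly between groups while age does not. Statistics recomputed "
      "from rounded summaries match raw-data values to about two decimals.")
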