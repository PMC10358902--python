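"""Hardy-Weinberg expectations, exact frequency tests, and effect sizes.

A SNP's cohort genotype counts are compared with the Hardy-Weinberg
expectation at its published population allele frequency by an exact
conditional test; a significant deviation flags the SNP for exclusion.
Cohen's d for a within-group change standardizes the mean change by the
group's baseline SD.
"""

from tgscore import cohens_d_change, fisher_exact_counts, hwe_expected
from tgscore.stats import random_hit_probability

# expected genotype counts at reference-allele proportion 0.7, cohort n = 45
exp = hwe_expected(0.7, 45)
print(f"HWE at p=0.7, n=45: ref-hom/het/alt-hom = {exp.rounded_counts()}")

# a cohort whose alternate allele is far too common
observed = (5, 15, 25)
res = fisher_exact_counts("rs_demo", observed, exp.rounded_counts())
print(f"observed {observed} vs expected {exp.rounded_counts()}: "
      f"exact p = {res.p_value:.2e}, excluded = {res.excluded}")

# effect sizes of the week-8 changes, standardized by baseline SD
for arm, change, base_sd in [("training", 0.23, 0.48), ("control", 0.03, 0.37)]:
    es = cohens_d_change(change, base_sd)
    print(f"{arm} arm: d = {es.d:.2f} ({es.label})")

# chance of the same gene clearing an alpha=0.05 screen three times
p3 = random_hit_probability(0.05, 3)
print(f"P(same gene flagged 3x at random) = {p3:.3g}; "
      f"expected rate over a 715-SNP panel = {random_hit_probability(0.05, 3, 715):.3f}")
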