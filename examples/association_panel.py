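"""Six-model case-control association from published genotype counts.

Builds the validation-cohort genotype count table for the AK5
c.1683_1684insATT locus (100 controls: 20/35/45; 100 celiac cases:
42/26/32), runs all six genetic-model contrasts and Hardy-Weinberg
tests, and prints the genotype/allelic distribution report.

With the wild-type genotype as the exposure, odds ratios above 1 mean
the wild-type class is enriched among cases — i.e. the insertion allele
is depleted in patients, consistent with a protective (risk-modifying)
role. The control mutant-allele frequency of 62.5% shows the globally
rare insertion is in fact common in this population.
"""

from famvar import run_full_panel, ak5_cohort_counts
from famvar.report import render_association_tsv

table = ak5_cohort_counts()
panel = run_full_panel(table)

print(render_association_tsv(panel))

for group in ("control", "case"):
    h = panel.hwe[group]
    print(
        f"HWE {group:7s}: mutant allele freq = {h.allele_freq:.3f}, "
        f"chi2 = {h.chi2:.3f} (df={h.df}), p = {h.p:.4f}"
    )
print(
    "\nA dominant-model chi2 of "
    f"{panel.result('dominant').chi2:.2f} (p = {panel.result('dominant').p:.1g}) "
    "indicates the genotype distributions of cases and controls differ well "
    "beyond sampling noise at this locus."
)
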