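"""Small published reference inputs used by examples and validation.

These are printed summary data (genotype counts), not raw study data;
they serve as inputs to the association panel.
"""

from .types import GenotypeCountTable


def ak5_cohort_counts() -> GenotypeCountTable:
    """Validation-cohort genotype counts for the AK5 c.1683_1684insATT locus.

    100 healthy controls (00/01/11 = 20/35/45) and 100 sporadic celiac
    cases (42/26/32), as reported in the study's genotype/allelic
    distribution table. Implied allele counts: controls 75 wild-type /
    125 mutant chromosomes, cases 110 / 90.
    """
    return GenotypeCountTable(
        n00_ctrl=20, n01_ctrl=35, n11_ctrl=45, n00_case=42, n01_case=26, n11_case=32
    )


__all__ = ["ak5_cohort_counts"]
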