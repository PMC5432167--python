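"""Case-control association at a single biallelic locus.

Six genetic-model contrasts are derived from a 2x3 genotype count table
(wild-type homozygote 00, heterozygote 01, mutant homozygote 11):

========================  =========================================
contrast                  2x2 comparison
========================  =========================================
het_vs_ref (codominant)   00 vs 01
hom_vs_ref (codominant)   00 vs 11
dominant                  00 vs 01+11
overdominant              01 vs 00+11
recessive                 11 vs 00+01
allelic                   allele 0 vs allele 1 (chromosome counts)
========================  =========================================

Each contrast is tested with the uncorrected Pearson chi-squared test
(df = 1) and summarized by the odds ratio with a Woolf (log-OR +/- 1.96
SE) 95% confidence interval. Hardy-Weinberg equilibrium is tested per
group by a chi-squared goodness of fit (df = 1, allele frequency
estimated from the data).

Orientation: with ``exposure="wildtype"`` (the default) the "exposed"
column is the wild-type reference class when it stands alone on one side
of the contrast (codominant, dominant, allelic) and the contrast's own
pure genotype class otherwise (overdominant: HET, recessive: mutant
homozygote). This orientation reports odds ratios above 1 when the
variant is depleted in cases — the natural framing for a candidate
protective allele. ``exposure="mutant"`` gives the reciprocal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .types import GenotypeCountTable, ValidationError

CONTRASTS = ("het_vs_ref", "hom_vs_ref", "dominant", "overdominant", "recessive", "allelic")

#: human-readable comparison labels, in report order
CONTRAST_LABELS = {
    "het_vs_ref": "01 vs 00",
    "hom_vs_ref": "11 vs 00",
    "dominant": "00 vs 01+11",
    "overdominant": "01 vs 00+11",
    "recessive": "11 vs 00+01",
    "allelic": "allele 0 vs 1",
}


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table with rows (case, control) and columns (exposed, unexposed)."""

    a: int  # case, exposed
    b: int  # case, unexposed
    c: int  # control, exposed
    d: int  # control, unexposed
    exposure_label: str = ""

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValidationError(f"cell {name} must be >= 0")
        if self.n < 1:
            raise ValidationError("2x2 table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row case, row control, col exposed, col unexposed) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def transposed_exposure(self) -> "TwoByTwo":
        return TwoByTwo(self.b, self.a, self.d, self.c, exposure_label=f"not {self.exposure_label}")


@dataclass(frozen=True)
class AssociationResult:
    contrast: str
    table: TwoByTwo
    chi2: float
    df: int
    p: float
    or_point: float
    ci_low: float
    ci_high: float
    method_notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValidationError("odds ratio outside its own confidence interval")


@dataclass(frozen=True)
class HweResult:
    allele_freq: float  # mutant-allele fraction
    expected: tuple[float, float, float]  # expected (n00, n01, n11)
    chi2: float
    df: int
    p: float


def _class_counts(counts: tuple[int, int, int], contrast: str) -> tuple[int, int, str, str]:
    """(exposed, unexposed) totals per group under wildtype orientation."""
    n00, n01, n11 = counts
    if contrast == "het_vs_ref":
        return n00, n01, "00", "01"
    if contrast == "hom_vs_ref":
        return n00, n11, "00", "11"
    if contrast == "dominant":
        return n00, n01 + n11, "00", "01+11"
    if contrast == "overdominant":
        return n01, n00 + n11, "01", "00+11"
    if contrast == "recessive":
        return n11, n00 + n01, "11", "00+01"
    if contrast == "allelic":
        return 2 * n00 + n01, 2 * n11 + n01, "allele 0", "allele 1"
    raise ValidationError(f"unknown contrast {contrast!r}")


def build_contrast(
    table: GenotypeCountTable, contrast: str, exposure: str = "wildtype"
) -> TwoByTwo:
    """Collapse a genotype count table into the 2x2 for one contrast.

    The allelic contrast counts chromosomes (2*hom + het per allele per
    group). A zero margin raises an error naming the contrast.
    """
    if exposure not in ("wildtype", "mutant"):
        raise ValidationError(f"unknown exposure {exposure!r}")
    case_e, case_u, label_e, label_u = _class_counts(table.cases(), contrast)
    ctrl_e, ctrl_u, _, _ = _class_counts(table.controls(), contrast)
    t = TwoByTwo(case_e, case_u, ctrl_e, ctrl_u, exposure_label=label_e)
    if exposure == "mutant":
        t = TwoByTwo(case_u, case_e, ctrl_u, ctrl_e, exposure_label=label_u)
    if 0 in t.margins:
        raise ValidationError(f"contrast {contrast!r} has a zero margin; test undefined")
    return t


def pearson_chi2(t: TwoByTwo, continuity: bool = False) -> tuple[float, int, float]:
    """Uncorrected (default) Pearson chi-squared test on a 2x2 table.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); with ``continuity``
    the Yates-corrected numerator n (|ad - bc| - n/2)^2 is used. Returns
    (chi2, df=1, two-sided p from the chi-squared survival function).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2, c1, c2 = t.margins
    if 0 in (r1, r2, c1, c2):
        raise ValidationError("2x2 table has a zero margin; chi-squared undefined")
    n = t.n
    delta = abs(a * d - b * c)
    if continuity:
        delta = max(0.0, delta - n / 2)
    chi2 = n * delta * delta / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), 1, p


def odds_ratio_woolf(t: TwoByTwo, zero_cell: str = "error") -> tuple[float, float, float]:
    """Odds ratio with Woolf 95% CI: exp(ln OR +/- 1.96 sqrt(sum 1/cell)).

    ``zero_cell="haldane"`` applies the Haldane-Anscombe correction
    (0.5 added to every cell) when any cell is zero; ``"error"`` raises.
    """
    cells = [t.a, t.b, t.c, t.d]
    if 0 in cells:
        if zero_cell == "haldane":
            cells = [x + 0.5 for x in cells]
        elif zero_cell == "error":
            raise ValidationError("2x2 table has an empty cell; use zero_cell='haldane'")
        else:
            raise ValidationError(f"unknown zero_cell policy {zero_cell!r}")
    a, b, c, d = cells
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = 1.959963984540054 * se  # standard normal 97.5% quantile
    log_or = math.log(or_point)
    return or_point, math.exp(log_or - half), math.exp(log_or + half)


def hwe_test(n00: int, n01: int, n11: int) -> HweResult:
    """Hardy-Weinberg chi-squared goodness of fit for one group.

    The mutant-allele fraction q = (2*n11 + n01) / (2n) is estimated
    from the observed counts; expected genotype counts are
    n * ((1-q)^2, 2q(1-q), q^2) and the statistic has df = 1
    (3 classes - 1 - 1 estimated parameter).
    """
    for name, v in (("n00", n00), ("n01", n01), ("n11", n11)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0")
    n = n00 + n01 + n11
    if n < 1:
        raise ValidationError("empty genotype counts; HWE test undefined")
    q = (2 * n11 + n01) / (2 * n)
    expected = (n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2)
    chi2 = 0.0
    for obs, exp in zip((n00, n01, n11), expected):
        if exp > 0:
            chi2 += (obs - exp) ** 2 / exp
        elif obs > 0:  # expected 0 but observed > 0 cannot happen with q from data
            chi2 = math.inf
    p = float(stats.chi2.sf(chi2, df=1))
    return HweResult(allele_freq=q, expected=expected, chi2=float(chi2), df=1, p=p)


@dataclass(frozen=True)
class AssociationPanel:
    """Full six-contrast panel plus per-group HWE results."""

    results: tuple[AssociationResult, ...]
    hwe: dict  # group name -> HweResult
    table: GenotypeCountTable

    def result(self, contrast: str) -> AssociationResult:
        for r in self.results:
            if r.contrast == contrast:
                return r
        raise KeyError(contrast)


def run_full_panel(
    table: GenotypeCountTable,
    exposure: str = "wildtype",
    continuity: bool = False,
    zero_cell: str = "error",
) -> AssociationPanel:
    """All six contrasts in report order, plus HWE per group."""
    if table.n_ctrl < 1 or table.n_case < 1:
        raise ValidationError("each group needs at least one genotyped individual")
    results = []
    for contrast in CONTRASTS:
        t = build_contrast(table, contrast, exposure=exposure)
        chi2, df, p = pearson_chi2(t, continuity=continuity)
        or_point, ci_low, ci_high = odds_ratio_woolf(t, zero_cell=zero_cell)
        results.append(
            AssociationResult(
                contrast=contrast,
                table=t,
                chi2=chi2,
                df=df,
                p=p,
                or_point=or_point,
                ci_low=ci_low,
                ci_high=ci_high,
                method_notes={
                    "continuity_correction": continuity,
                    "ci_method": "Woolf",
                    "zero_cell_correction": zero_cell == "haldane" and 0 in (t.a, t.b, t.c, t.d),
                    "exposure": exposure,
                },
            )
        )
    hwe = {
        "control": hwe_test(*table.controls()),
        "case": hwe_test(*table.cases()),
    }
    return AssociationPanel(results=tuple(results), hwe=hwe, table=table)


__all__ = [
    "CONTRASTS",
    "CONTRAST_LABELS",
    "TwoByTwo",
    "AssociationResult",
    "HweResult",
    "AssociationPanel",
    "build_contrast",
    "pearson_chi2",
    "odds_ratio_woolf",
    "hwe_test",
    "run_full_panel",
]
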