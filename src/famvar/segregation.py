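"""Mendelian segregation screening on a pedigree.

Two inheritance models for a fully penetrant recessive disorder:

* **Autosomal recessive (AR)** — every affected individual is homozygous
  for the alternate allele, each parent of an affected is an obligate
  heterozygous carrier, and no unaffected member is homozygous-alternate.
* **Compound heterozygote (CH)** — an affected individual carries two
  different damaging alleles of the same gene in *trans*, one inherited
  from each parent. Phase is established strictly from parental
  genotypes: pairs whose phase cannot be resolved (both parents
  heterozygous for both variants, plausible under consanguinity) are
  reported as indeterminate, never consistent.

Only autosomal variants are screened; sex-chromosome and mitochondrial
records are excluded with a logged notice. Verdicts do not depend on
sample or variant ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from .types import (
    AnnotatedVariant,
    Genotype,
    GenotypeMatrix,
    Pedigree,
    ValidationError,
    is_autosomal,
)

logger = logging.getLogger(__name__)

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class SegregationResult:
    """Verdict for one AR variant or one CH variant pair."""

    model: str  # "AR" or "CH"
    variants: tuple[AnnotatedVariant, ...]
    evidence: dict[str, Genotype] | tuple  # sample_id -> genotype (CH: per-variant tuple of maps)
    verdict: str

    def __post_init__(self) -> None:
        if self.model == "AR" and len(self.variants) != 1:
            raise ValidationError("AR result must reference exactly 1 variant")
        if self.model == "CH":
            if len(self.variants) != 2 or self.variants[0] == self.variants[1]:
                raise ValidationError("CH result must reference exactly 2 distinct variants")
            if self.variants[0].gene != self.variants[1].gene or self.variants[0].gene is None:
                raise ValidationError("CH pair must share a gene symbol")

    @property
    def sort_key(self) -> tuple:
        v = min(self.variants, key=lambda x: (x.chrom, x.pos, x.alt))
        return (v.chrom, v.pos, v.alt)


def _members_in_matrix(pedigree: Pedigree, matrix: GenotypeMatrix) -> list[str]:
    present = set(matrix.samples)
    return [m.sample_id for m in pedigree.members if m.sample_id in present]


def _require_affected_present(pedigree: Pedigree, matrix: GenotypeMatrix) -> list[str]:
    affected = pedigree.affected_ids
    if not affected:
        raise ValidationError("pedigree has no affected member; segregation analysis undefined")
    missing = [sid for sid in affected if sid not in matrix.samples]
    if missing:
        raise ValidationError(f"affected member(s) absent from genotype matrix: {', '.join(missing)}")
    return affected


def ar_consistent(
    variant_index: int,
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    missing_policy: str = "strict",
) -> SegregationResult:
    """Test one variant against the autosomal-recessive model.

    Requirements for a ``consistent`` verdict: every affected HOM_ALT,
    every genotyped parent of an affected HET, every genotyped unaffected
    member HOM_REF or HET. A missing genotype makes the verdict
    ``indeterminate`` under the ``strict`` policy (ranked as
    non-consistent) and is ignored for that member under ``permissive``.
    """
    if missing_policy not in ("strict", "permissive"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    affected = _require_affected_present(pedigree, matrix)
    genotypes = matrix.genotypes(variant_index)
    members = _members_in_matrix(pedigree, matrix)
    evidence = {sid: genotypes[sid] for sid in members}

    parent_ids = sorted({p for sid in affected for p in pedigree.parents_of(sid) if p in genotypes})
    unaffected = [sid for sid in pedigree.unaffected_ids if sid in genotypes]

    saw_missing = False

    def check(sid: str, allowed: set[Genotype]) -> bool | None:
        """True=ok, False=violation, None=missing."""
        g = genotypes[sid]
        if g is Genotype.MISSING:
            return None
        return g in allowed

    checks = (
        [(sid, {Genotype.HOM_ALT}) for sid in affected]
        + [(sid, {Genotype.HET}) for sid in parent_ids]
        + [(sid, {Genotype.HOM_REF, Genotype.HET}) for sid in unaffected if sid not in parent_ids]
    )
    verdict = CONSISTENT
    for sid, allowed in checks:
        result = check(sid, allowed)
        if result is False:
            verdict = INCONSISTENT
            break
        if result is None:
            saw_missing = True
    else:
        if saw_missing and missing_policy == "strict":
            verdict = INDETERMINATE

    return SegregationResult(
        model="AR", variants=(matrix.variants[variant_index],), evidence=evidence, verdict=verdict
    )


def _ch_pair_verdict(
    g1: dict[str, Genotype],
    g2: dict[str, Genotype],
    affected: list[str],
    father: str | None,
    mother: str | None,
    unaffected: list[str],
    missing_policy: str,
) -> str:
    """Verdict for one candidate compound-het pair (order-free in v1/v2)."""
    relevant = list(affected) + [p for p in (father, mother) if p is not None] + list(unaffected)
    if missing_policy == "strict":
        for sid in relevant:
            if g1.get(sid, Genotype.MISSING) is Genotype.MISSING or g2.get(sid, Genotype.MISSING) is Genotype.MISSING:
                return INDETERMINATE

    def gt(g: dict[str, Genotype], sid: str) -> Genotype:
        return g.get(sid, Genotype.MISSING)

    # every affected heterozygous for both members of the pair
    for sid in affected:
        for g in (g1, g2):
            code = gt(g, sid)
            if code is Genotype.MISSING:
                continue  # permissive only; strict returned above
            if code is not Genotype.HET:
                return INCONSISTENT
    if father is None or mother is None:
        return INDETERMINATE  # trans phase cannot be established
    f1, f2 = gt(g1, father), gt(g2, father)
    m1, m2 = gt(g1, mother), gt(g2, mother)
    # parents homozygous-alt would be affected under full penetrance
    if Genotype.HOM_ALT in (f1, f2, m1, m2):
        return INCONSISTENT
    # possible parental origins of the single alt allele of each variant:
    # only a heterozygous-carrier parent can have transmitted it
    origins1 = {p for p, g in (("father", f1), ("mother", m1)) if g is Genotype.HET}
    origins2 = {p for p, g in (("father", f2), ("mother", m2)) if g is Genotype.HET}
    if not origins1 or not origins2:
        return INCONSISTENT  # allele unexplained by either parent (de novo)
    assignments = {(o1, o2) for o1 in origins1 for o2 in origins2}
    trans = {a for a in assignments if a[0] != a[1]}
    if not trans:
        return INCONSISTENT  # cis with certainty: both alleles from one parent
    if trans != assignments:
        return INDETERMINATE  # phase ambiguous: a cis explanation also exists
    # no unaffected member may carry both alleles of the pair
    for sid in unaffected:
        c1, c2 = gt(g1, sid), gt(g2, sid)
        if c1 in (Genotype.HET, Genotype.HOM_ALT) and c2 in (Genotype.HET, Genotype.HOM_ALT):
            return INCONSISTENT
    return CONSISTENT


def ch_candidates(
    gene: str,
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    missing_policy: str = "strict",
) -> list[SegregationResult]:
    """Compound-heterozygote candidate pairs within one gene.

    Returns consistent pairs plus phase-ambiguous (indeterminate) ones;
    pairs violating any clause are omitted. A gene with fewer than two
    variants yields an empty list.
    """
    affected = _require_affected_present(pedigree, matrix)
    indices = [
        i
        for i, v in enumerate(matrix.variants)
        if v.gene == gene and is_autosomal(v.chrom)
    ]
    if len(indices) < 2:
        return []
    # one (father, mother) pair is required; take it from the first affected
    proband = pedigree.member(affected[0])
    father = proband.father_id if proband.father_id in matrix.samples else None
    mother = proband.mother_id if proband.mother_id in matrix.samples else None
    unaffected = [sid for sid in pedigree.unaffected_ids if sid in matrix.samples]

    results: list[SegregationResult] = []
    for i, j in combinations(indices, 2):
        # canonical within-pair order so results are input-order independent
        vi, vj = matrix.variants[i], matrix.variants[j]
        if (vj.chrom, vj.pos, vj.alt) < (vi.chrom, vi.pos, vi.alt):
            i, j, vi, vj = j, i, vj, vi
        g1, g2 = matrix.genotypes(i), matrix.genotypes(j)
        verdict = _ch_pair_verdict(g1, g2, affected, father, mother, unaffected, missing_policy)
        if verdict is INCONSISTENT:
            continue
        results.append(
            SegregationResult(model="CH", variants=(vi, vj), evidence=(g1, g2), verdict=verdict)
        )
    results.sort(key=lambda r: r.sort_key)
    return results


def screen_family(
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    missing_policy: str = "strict",
    models: tuple[str, ...] = ("AR", "CH"),
) -> list[SegregationResult]:
    """Screen a filtered matrix for AR-consistent variants and CH pairs.

    Returns consistent results only — AR first, then CH — in a
    deterministic (chrom, pos, alt) order with full per-sample evidence.
    """
    _require_affected_present(pedigree, matrix)
    results: list[SegregationResult] = []
    non_autosomal = [v.key for v in matrix.variants if not is_autosomal(v.chrom)]
    if non_autosomal:
        logger.info("excluding %d non-autosomal variant(s) from segregation screening", len(non_autosomal))
    if "AR" in models:
        ar_hits = [
            ar_consistent(i, matrix, pedigree, missing_policy)
            for i, v in enumerate(matrix.variants)
            if is_autosomal(v.chrom)
        ]
        results.extend(sorted((r for r in ar_hits if r.verdict == CONSISTENT), key=lambda r: r.sort_key))
    if "CH" in models:
        genes = sorted({v.gene for v in matrix.variants if v.gene is not None and is_autosomal(v.chrom)})
        ch_hits: list[SegregationResult] = []
        for gene in genes:
            ch_hits.extend(r for r in ch_candidates(gene, matrix, pedigree, missing_policy) if r.verdict == CONSISTENT)
        results.extend(sorted(ch_hits, key=lambda r: r.sort_key))
    return results


__all__ = [
    "SegregationResult",
    "ar_consistent",
    "ch_candidates",
    "screen_family",
    "CONSISTENT",
    "INCONSISTENT",
    "INDETERMINATE",
]
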