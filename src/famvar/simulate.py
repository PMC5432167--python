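"""Synthetic cohorts and family exomes with planted inheritance signals.

Everything the pipeline consumes can be generated here, so every stage
is testable without external data:

* :func:`simulate_cohort` draws case/control genotype counts at one
  locus. Controls follow Hardy-Weinberg proportions at a specified
  allele frequency; case genotype probabilities are the control ones
  tilted by genotype relative risks and renormalized — the simplest
  structure able to reproduce an observed case genotype distribution.
* :func:`simulate_family_vcf` builds a multi-sample exome-like VCF and
  PED for a nuclear family: founder genotypes drawn from per-variant
  population frequencies, children by Mendelian transmission, decoy
  variants constructed to fail a named filter stage (or to pass all
  filters but fail segregation), and planted variants overwritten to
  exactly match an autosomal-recessive or compound-heterozygote pattern.
  The emitted truth table is the oracle for recovery tests.

All randomness flows through an explicit integer seed; identical seeds
give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    Affection,
    AnnotatedVariant,
    Consequence,
    Genotype,
    GenotypeCall,
    GenotypeCountTable,
    GenotypeMatrix,
    PedMember,
    Pedigree,
    Region,
    Sex,
    ValidationError,
)
from .segregation import ar_consistent, CONSISTENT
from . import vcfio

FAIL_STAGES = ("none", "quality", "consequence", "rarity", "deleterious")


def _sig6(x: float) -> float:
    return float(format(float(x), ".6g"))


def study_pedigree(sequenced_only: bool = False) -> Pedigree:
    """The study-family shape: consanguineous nuclear family, 2 affected.

    Seven members — parents III-1/III-2 plus five children IV-1..IV-5,
    of whom IV-3 and IV-4 are affected. With ``sequenced_only`` the
    pedigree is restricted to the five exome-sequenced individuals
    (both parents, both affected children, one healthy sibling).
    """
    father, mother = "III-1", "III-2"
    members = [
        PedMember(father, None, None, Sex.MALE, Affection.UNAFFECTED),
        PedMember(mother, None, None, Sex.FEMALE, Affection.UNAFFECTED),
        PedMember("IV-1", father, mother, Sex.MALE, Affection.UNAFFECTED),
        PedMember("IV-2", father, mother, Sex.FEMALE, Affection.UNAFFECTED),
        PedMember("IV-3", father, mother, Sex.FEMALE, Affection.AFFECTED),
        PedMember("IV-4", father, mother, Sex.FEMALE, Affection.AFFECTED),
        PedMember("IV-5", father, mother, Sex.MALE, Affection.UNAFFECTED),
    ]
    if sequenced_only:
        keep = {father, mother, "IV-1", "IV-3", "IV-4"}
        members = [m for m in members if m.sample_id in keep]
    return Pedigree(members=members)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """One-locus case/control cohort under a genotype-relative-risk model.

    Defaults mirror the validation cohort: 100 cases, 100 controls,
    control mutant-allele frequency 0.625 under Hardy-Weinberg. Case
    genotype probabilities are proportional to
    (p00, p01 * r_het, p11 * r_hom), renormalized.
    """

    seed: int
    n_cases: int = 100
    n_controls: int = 100
    allele_freq_controls: float = 0.625
    genotype_relative_risks: tuple[float, float] = (1.0, 1.0)
    hwe: bool = True
    control_genotype_probs: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_freq_controls <= 1.0:
            raise ValidationError("allele_freq_controls must lie in [0, 1]")
        if min(self.genotype_relative_risks) < 0:
            raise ValidationError("genotype relative risks must be >= 0")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("both groups need at least one individual")
        if not self.hwe and self.control_genotype_probs is None:
            raise ValidationError("hwe=False requires explicit control_genotype_probs")


@dataclass(frozen=True)
class CohortSim:
    table: GenotypeCountTable
    control_genotypes: tuple[Genotype, ...]
    case_genotypes: tuple[Genotype, ...]


def hwe_probs(q: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2)."""
    return ((1 - q) ** 2, 2 * q * (1 - q), q**2)


def case_probs(control: tuple[float, float, float], r_het: float, r_hom: float) -> tuple[float, float, float]:
    raw = (control[0], control[1] * r_het, control[2] * r_hom)
    total = sum(raw)
    if total <= 0:
        raise ValidationError("degenerate case genotype probabilities (all zero)")
    return tuple(x / total for x in raw)  # type: ignore[return-value]


def relative_risks_for_case_fractions(
    q: float, case_fractions: tuple[float, float, float]
) -> tuple[float, float]:
    """Genotype relative risks whose expected case fractions match a target.

    Solves (p00, p01*r_het, p11*r_hom) proportional to ``case_fractions``
    for HWE control probabilities at allele frequency ``q``.
    """
    p00, p01, p11 = hwe_probs(q)
    f00, f01, f11 = case_fractions
    if p00 <= 0 or f00 <= 0:
        raise ValidationError("reference genotype class must have positive probability")
    r_het = (f01 / f00) / (p01 / p00) if p01 > 0 else 0.0
    r_hom = (f11 / f00) / (p11 / p00) if p11 > 0 else 0.0
    return (r_het, r_hom)


_GENO_ORDER = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)


def simulate_cohort(spec: CohortSpec) -> CohortSim:
    """Draw one cohort; multinomial genotype sampling per group."""
    rng = np.random.default_rng(spec.seed)
    control_p = (
        hwe_probs(spec.allele_freq_controls) if spec.hwe else tuple(spec.control_genotype_probs)  # type: ignore[arg-type]
    )
    if sum(control_p) <= 0:
        raise ValidationError("degenerate control genotype probabilities (all zero)")
    control_p = tuple(x / sum(control_p) for x in control_p)
    case_p = case_probs(control_p, *spec.genotype_relative_risks)
    ctrl_counts = rng.multinomial(spec.n_controls, control_p)
    case_counts = rng.multinomial(spec.n_cases, case_p)
    table = GenotypeCountTable(
        n00_ctrl=int(ctrl_counts[0]),
        n01_ctrl=int(ctrl_counts[1]),
        n11_ctrl=int(ctrl_counts[2]),
        n00_case=int(case_counts[0]),
        n01_case=int(case_counts[1]),
        n11_case=int(case_counts[2]),
    )
    control_genotypes = tuple(g for g, k in zip(_GENO_ORDER, ctrl_counts) for _ in range(k))
    case_genotypes = tuple(g for g, k in zip(_GENO_ORDER, case_counts) for _ in range(k))
    return CohortSim(table=table, control_genotypes=control_genotypes, case_genotypes=case_genotypes)


# ---------------------------------------------------------------------------
# family exome simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSignal:
    """One planted inheritance signal: an AR variant or a CH pair."""

    model: str  # "AR" or "CH"
    gene: str

    def __post_init__(self) -> None:
        if self.model not in ("AR", "CH"):
            raise ValidationError(f"unknown planted model {self.model!r}")


@dataclass(frozen=True)
class PlantSpec:
    """Specification of a synthetic family exome.

    ``n_decoys`` background variants are spread uniformly over the decoy
    fail-stage classes given by ``decoy_stage_fractions`` (``"none"``
    decoys pass every filter but are guaranteed non-segregating).
    Annotation values are drawn per class: population MAF is absent with
    probability ``maf_absent_fraction``, otherwise log-uniform inside
    the rare range (or the common range for rarity-failing decoys);
    SIFT/PolyPhen are uniform within their damaging or benign intervals.
    """

    seed: int
    pedigree: Pedigree = field(default_factory=study_pedigree)
    n_decoys: int = 500
    planted: tuple[PlantedSignal, ...] = (PlantedSignal("AR", "GENE_AR"),)
    decoy_stage_fractions: dict = field(
        default_factory=lambda: {s: 1 / len(FAIL_STAGES) for s in FAIL_STAGES}
    )
    maf_absent_fraction: float = 0.5
    rare_maf_range: tuple[float, float] = (1e-8, 5e-5)
    common_maf_range: tuple[float, float] = (1e-3, 0.5)
    population_allele_freq_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.n_decoys < 0:
            raise ValidationError("n_decoys must be >= 0")
        unknown = set(self.decoy_stage_fractions) - set(FAIL_STAGES)
        if unknown:
            raise ValidationError(f"unknown decoy fail stage(s): {sorted(unknown)}")
        if self.planted and not self.pedigree.affected_ids:
            raise ValidationError("cannot plant an inheritance signal: pedigree has no affected member")


@dataclass
class FamilySim:
    matrix: GenotypeMatrix
    pedigree: Pedigree
    truth: pd.DataFrame  # columns: key, gene, kind, model, fail_stage


def _draw_genotype(rng: np.random.Generator, q: float) -> Genotype:
    return _GENO_ORDER[int(rng.choice(3, p=hwe_probs(q)))]


def _transmit(rng: np.random.Generator, father: Genotype, mother: Genotype) -> Genotype:
    """Mendelian transmission: one allele from each parent, each of the
    parent's two alleles with probability 1/2."""
    def gamete(g: Genotype) -> int:
        k = g.alt_count
        if k == 0:
            return 0
        if k == 2:
            return 1
        return int(rng.integers(0, 2))

    total = gamete(father) + gamete(mother)
    return _GENO_ORDER[total]


def _good_call(sample_id: str, code: Genotype, rng: np.random.Generator) -> GenotypeCall:
    return GenotypeCall(sample_id=sample_id, code=code, depth=int(rng.integers(40, 120)), gq=float(rng.integers(60, 100)))


def _family_genotypes(
    rng: np.random.Generator, pedigree: Pedigree, q: float
) -> dict[str, Genotype]:
    """Founder draws + Mendelian transmission down the pedigree."""
    out: dict[str, Genotype] = {}

    def resolve(sid: str) -> Genotype:
        if sid in out:
            return out[sid]
        m = pedigree.member(sid)
        if m.father_id is None or m.mother_id is None:
            g = _draw_genotype(rng, q)
        else:
            g = _transmit(rng, resolve(m.father_id), resolve(m.mother_id))
        out[sid] = g
        return g

    for m in pedigree.members:
        resolve(m.sample_id)
    return out


def _decoy_annotations(
    rng: np.random.Generator, fail_stage: str, spec: PlantSpec
) -> dict:
    """Annotation fields making a decoy pass every stage before, and fail
    exactly at, its labelled stage."""
    lo, hi = spec.rare_maf_range
    clo, chi = spec.common_maf_range

    def log_uniform(low: float, high: float) -> float:
        return _sig6(float(np.exp(rng.uniform(np.log(low), np.log(high)))))

    ann: dict = {
        "site_qual": _sig6(float(rng.uniform(45, 90))),
        "both_strands": bool(rng.integers(0, 2)),
        "region": Region.EXONIC,
        "consequence": Consequence.MISSENSE,
        "pop_freqs": {},
        "sift": None,
        "polyphen": None,
    }
    if rng.random() > spec.maf_absent_fraction:
        ann["pop_freqs"] = {"exac": log_uniform(lo, hi)}
    # damaging scores so the deleterious stage passes by default
    ann["sift"] = _sig6(float(rng.uniform(0.0, 0.05)))
    ann["polyphen"] = _sig6(float(rng.uniform(0.5, 1.0)))

    if fail_stage == "quality":
        ann["site_qual"] = _sig6(float(rng.uniform(5, 29)))  # below both thresholds
    elif fail_stage == "consequence":
        if rng.random() < 0.5:
            ann["consequence"] = Consequence.SYNONYMOUS
        else:
            ann["region"] = Region(str(rng.choice(["intronic", "intergenic"])))
    elif fail_stage == "rarity":
        ann["pop_freqs"] = {"exac": log_uniform(clo, chi)}
    elif fail_stage == "deleterious":
        ann["sift"] = _sig6(float(rng.uniform(0.2, 1.0)))  # benign by both tools
        ann["polyphen"] = _sig6(float(rng.uniform(0.0, 0.45)))
    return ann


_BASES = ("A", "C", "G", "T")


def _random_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice([b for b in _BASES if b != ref]))
    return ref, alt


def _ar_pattern(rng: np.random.Generator, pedigree: Pedigree) -> dict[str, Genotype]:
    """Exact AR genotype pattern: parents HET, affected HOM_ALT,
    unaffected siblings HET or HOM_REF (either is Mendelian-legal)."""
    out: dict[str, Genotype] = {}
    parent_ids = {p for sid in pedigree.affected_ids for p in pedigree.parents_of(sid)}
    for m in pedigree.members:
        if m.sample_id in parent_ids:
            out[m.sample_id] = Genotype.HET
        elif m.affection is Affection.AFFECTED:
            out[m.sample_id] = Genotype.HOM_ALT
        else:
            out[m.sample_id] = Genotype.HET if rng.random() < 0.5 else Genotype.HOM_REF
    return out


def _ch_patterns(
    rng: np.random.Generator, pedigree: Pedigree
) -> tuple[dict[str, Genotype], dict[str, Genotype]]:
    """Trans compound-het pair: one allele paternal, the other maternal;
    affected HET for both; no unaffected member carries both."""
    affected = pedigree.affected_ids
    proband = pedigree.member(affected[0])
    father, mother = proband.father_id, proband.mother_id
    if father is None or mother is None:
        raise ValidationError("CH plant requires both parents in the pedigree")
    g1: dict[str, Genotype] = {}
    g2: dict[str, Genotype] = {}
    for m in pedigree.members:
        sid = m.sample_id
        if sid == father:
            g1[sid], g2[sid] = Genotype.HET, Genotype.HOM_REF
        elif sid == mother:
            g1[sid], g2[sid] = Genotype.HOM_REF, Genotype.HET
        elif m.affection is Affection.AFFECTED:
            g1[sid], g2[sid] = Genotype.HET, Genotype.HET
        else:
            # carry at most one member of the pair
            choice = rng.integers(0, 3)  # 0: neither, 1: paternal only, 2: maternal only
            g1[sid] = Genotype.HET if choice == 1 else Genotype.HOM_REF
            g2[sid] = Genotype.HET if choice == 2 else Genotype.HOM_REF
    return g1, g2


def simulate_family(spec: PlantSpec) -> FamilySim:
    """Build the in-memory family exome matrix plus its truth table."""
    rng = np.random.default_rng(spec.seed)
    pedigree = spec.pedigree
    samples = [m.sample_id for m in pedigree.members]

    # decoy stage assignment: deterministic proportional split, remainder
    # to the 'none' class so totals always equal n_decoys
    fractions = spec.decoy_stage_fractions
    total_frac = sum(fractions.values())
    stage_counts: dict[str, int] = {}
    assigned = 0
    for stage in FAIL_STAGES:
        if stage == "none":
            continue
        k = int(round(spec.n_decoys * fractions.get(stage, 0.0) / total_frac)) if total_frac else 0
        stage_counts[stage] = k
        assigned += k
    stage_counts["none"] = max(0, spec.n_decoys - assigned)

    records: list[tuple[AnnotatedVariant, dict[str, Genotype], dict]] = []
    truth_rows: list[dict] = []

    used_positions: set[tuple[str, int]] = set()

    def fresh_position(chrom: str) -> int:
        while True:
            pos = int(rng.integers(10_000, 200_000_000))
            if (chrom, pos) not in used_positions:
                used_positions.add((chrom, pos))
                return pos

    decoy_index = 0
    for stage in FAIL_STAGES:
        for _ in range(stage_counts.get(stage, 0)):
            decoy_index += 1
            chrom = str(1 + (decoy_index % 22))
            pos = fresh_position(chrom)
            ref, alt = _random_snv_alleles(rng)
            ann = _decoy_annotations(rng, stage, spec)
            q = _sig6(float(rng.uniform(*spec.population_allele_freq_range)))
            genotypes = _family_genotypes(rng, pedigree, q)
            variant = AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=f"DECOY{decoy_index:05d}",
                region=ann["region"],
                consequence=ann["consequence"],
                pop_freqs=ann["pop_freqs"],
                sift=ann["sift"],
                polyphen=ann["polyphen"],
                site_qual=ann["site_qual"],
                both_strands=ann["both_strands"],
            )
            if stage == "none":
                # a pass-all decoy must fail at segregation, not by luck:
                # resample transmissions until the AR pattern is broken
                for _attempt in range(100):
                    if not _is_ar_pattern(genotypes, pedigree):
                        break
                    genotypes = _family_genotypes(rng, pedigree, q)
                else:  # pragma: no cover - ~0 probability
                    raise ValidationError("could not draw a non-segregating pass-all decoy")
            records.append((variant, genotypes, {"kind": "decoy", "model": "", "fail_stage": stage}))

    for plant_index, plant in enumerate(spec.planted):
        chrom = str(1 + (plant_index % 22))
        if plant.model == "AR":
            pos = fresh_position(chrom)
            # an in-frame 3-bp insertion, the shape of the index family's hit
            variant = AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref="T",
                alt="TATT",
                gene=plant.gene,
                region=Region.EXONIC,
                consequence=Consequence.INFRAME_INDEL,
                pop_freqs={},
                sift=None,
                polyphen=None,
                site_qual=75.0,
                both_strands=True,
            )
            records.append(
                (variant, _ar_pattern(rng, pedigree), {"kind": "planted", "model": "AR", "fail_stage": "none"})
            )
        else:  # CH pair
            g1, g2 = _ch_patterns(rng, pedigree)
            for g, offset in ((g1, 0), (g2, 1)):
                pos = fresh_position(chrom)
                ref, alt = _random_snv_alleles(rng)
                variant = AnnotatedVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=plant.gene,
                    region=Region.EXONIC,
                    consequence=Consequence.MISSENSE,
                    pop_freqs={"exac": 1e-5},
                    sift=0.01,
                    polyphen=0.95,
                    site_qual=70.0,
                    both_strands=True,
                )
                records.append((variant, g, {"kind": "planted", "model": "CH", "fail_stage": "none"}))

    def chrom_rank(c: str) -> int:
        return int(c.removeprefix("chr")) if c.removeprefix("chr").isdigit() else 99

    records.sort(key=lambda r: (chrom_rank(r[0].chrom), r[0].pos, r[0].alt))

    variants = [r[0] for r in records]
    calls: list[list[GenotypeCall]] = []
    for variant, genotypes, meta in records:
        row = [_good_call(sid, genotypes[sid], rng) for sid in samples]
        calls.append(row)
        truth_rows.append(
            {
                "key": variant.key,
                "gene": variant.gene,
                "kind": meta["kind"],
                "model": meta["model"],
                "fail_stage": meta["fail_stage"],
            }
        )
    matrix = GenotypeMatrix(variants=variants, samples=samples, calls=calls)
    truth = pd.DataFrame(truth_rows, columns=["key", "gene", "kind", "model", "fail_stage"])
    return FamilySim(matrix=matrix, pedigree=pedigree, truth=truth)


def _is_ar_pattern(genotypes: dict[str, Genotype], pedigree: Pedigree) -> bool:
    parent_ids = {p for sid in pedigree.affected_ids for p in pedigree.parents_of(sid)}
    for m in pedigree.members:
        g = genotypes[m.sample_id]
        if m.sample_id in parent_ids:
            if g is not Genotype.HET:
                return False
        elif m.affection is Affection.AFFECTED:
            if g is not Genotype.HOM_ALT:
                return False
        elif m.affection is Affection.UNAFFECTED and g is Genotype.HOM_ALT:
            return False
    return True


def simulate_family_vcf(spec: PlantSpec, out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write the simulated family as VCF + PED + truth TSV.

    Files round-trip through the package's own readers; identical seeds
    give byte-identical output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_family(spec)
    vcf_path = vcfio.write_vcf(sim.matrix, out_dir / "family.vcf")
    ped_path = vcfio.write_ped(sim.pedigree, out_dir / "family.ped")
    truth_path = out_dir / "truth.tsv"
    sim.truth.to_csv(truth_path, sep="\t", index=False)
    return vcf_path, ped_path, truth_path


__all__ = [
    "CohortSpec",
    "CohortSim",
    "PlantSpec",
    "PlantedSignal",
    "FamilySim",
    "FAIL_STAGES",
    "study_pedigree",
    "hwe_probs",
    "case_probs",
    "relative_risks_for_case_fractions",
    "simulate_cohort",
    "simulate_family",
    "simulate_family_vcf",
]
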