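"""Variant prioritization cascade: quality -> consequence -> rarity -> deleteriousness.

The cascade keeps exonic / UTR / splice variants that are novel or
extremely rare in population databases and not jointly predicted benign
by SIFT and PolyPhen-2, after discarding low-confidence sites and
degrading low-quality genotype calls to missing. Each stage records how
many variants it removed; a variant is attributed to the first stage it
fails, but the surviving set is the intersection of the per-stage pass
sets, so stage order never changes the outcome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

from .types import (
    AnnotatedVariant,
    Consequence,
    Genotype,
    GenotypeCall,
    GenotypeMatrix,
    Region,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_REGIONS = frozenset({Region.EXONIC, Region.UTR3, Region.UTR5, Region.SPLICE})
DEFAULT_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
        Consequence.SPLICE_SITE,
        Consequence.UTR,
        Consequence.UNKNOWN,
    }
)

STAGES = ("quality", "consequence", "rarity", "deleterious")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the prioritization cascade.

    Site quality is Phred-scaled: a site needs quality >= 40, or >= 30
    when the alternate was seen on both strands. Genotype calls below the
    GQ/depth floors are degraded to missing rather than discarding the
    site. ``max_maf`` is the "extremely rare" cutoff (default 0.005%,
    i.e. 5e-5) applied to every population frequency source present;
    ``common_maf_cutoff`` is the coarse 1% common-variant pre-filter.
    Deleteriousness excludes a variant only when SIFT and PolyPhen-2
    *both* predict benign; variants lacking either score (e.g. indels)
    pass.
    """

    min_site_qual_single_strand: float = 40.0
    min_site_qual_both_strands: float = 30.0
    min_gq: float = 30.0
    min_depth: int = 30
    max_maf: float = 5e-5
    common_maf_cutoff: float = 0.01
    allowed_regions: frozenset[Region] = DEFAULT_REGIONS
    allowed_consequences: frozenset[Consequence] = DEFAULT_CONSEQUENCES
    sift_deleterious_max: float = 0.05
    polyphen_deleterious_min: float = 0.5
    require_deleterious: bool = True

    def __post_init__(self) -> None:
        if self.max_maf > self.common_maf_cutoff:
            raise ValidationError(
                f"max_maf ({self.max_maf}) must not exceed common_maf_cutoff ({self.common_maf_cutoff})"
            )
        for name in ("min_site_qual_single_strand", "min_site_qual_both_strands", "min_gq"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.min_depth < 0:
            raise ValidationError("min_depth must be >= 0")
        for name in ("max_maf", "common_maf_cutoff", "sift_deleterious_max", "polyphen_deleterious_min"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")

    @classmethod
    def disabled(cls) -> "FilterConfig":
        """A configuration under which the cascade is the identity."""
        return cls(
            min_site_qual_single_strand=0.0,
            min_site_qual_both_strands=0.0,
            min_gq=0.0,
            min_depth=0,
            max_maf=1.0,
            common_maf_cutoff=1.0,
            allowed_regions=frozenset(Region),
            allowed_consequences=frozenset(Consequence),
            require_deleterious=False,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "FilterConfig":
        kwargs = dict(data)
        if "allowed_regions" in kwargs:
            kwargs["allowed_regions"] = frozenset(Region(r) for r in kwargs["allowed_regions"])
        if "allowed_consequences" in kwargs:
            kwargs["allowed_consequences"] = frozenset(Consequence(c) for c in kwargs["allowed_consequences"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "min_site_qual_single_strand": self.min_site_qual_single_strand,
            "min_site_qual_both_strands": self.min_site_qual_both_strands,
            "min_gq": self.min_gq,
            "min_depth": self.min_depth,
            "max_maf": self.max_maf,
            "common_maf_cutoff": self.common_maf_cutoff,
            "allowed_regions": sorted(r.value for r in self.allowed_regions),
            "allowed_consequences": sorted(c.value for c in self.allowed_consequences),
            "sift_deleterious_max": self.sift_deleterious_max,
            "polyphen_deleterious_min": self.polyphen_deleterious_min,
            "require_deleterious": self.require_deleterious,
        }


@dataclass(frozen=True)
class StageCount:
    stage: str
    n_in: int
    n_removed: int
    n_out: int

    def __post_init__(self) -> None:
        if self.n_in - self.n_removed != self.n_out:
            raise ValidationError(f"stage {self.stage}: {self.n_in} - {self.n_removed} != {self.n_out}")


@dataclass
class FilterReport:
    """Per-stage accounting for one cascade run."""

    stages: list[StageCount]
    passed: list[str] = field(default_factory=list)  # surviving variant keys

    def removed_at(self, stage: str) -> int:
        for s in self.stages:
            if s.stage == stage:
                return s.n_removed
        raise KeyError(stage)

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": [
                    {"stage": s.stage, "n_in": s.n_in, "n_removed": s.n_removed, "n_out": s.n_out}
                    for s in self.stages
                ],
                "passed": self.passed,
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["stage\tn_in\tn_removed\tn_out"]
        lines += [f"{s.stage}\t{s.n_in}\t{s.n_removed}\t{s.n_out}" for s in self.stages]
        return "\n".join(lines) + "\n"


def degrade_low_quality_calls(
    calls: Sequence[GenotypeCall], cfg: FilterConfig
) -> list[GenotypeCall]:
    """Set calls below the GQ/depth floors (or lacking them) to MISSING.

    The site itself is judged separately; failing genotypes are handed to
    the segregation logic as missing rather than discarding the site.
    """
    out: list[GenotypeCall] = []
    for call in calls:
        if call.code is Genotype.MISSING:
            out.append(call)
            continue
        ok = (
            call.gq is not None
            and call.depth is not None
            and call.gq >= cfg.min_gq
            and call.depth >= cfg.min_depth
        )
        if ok:
            out.append(call)
        else:
            logger.debug("degrading call for %s to MISSING (DP=%s GQ=%s)", call.sample_id, call.depth, call.gq)
            out.append(replace(call, code=Genotype.MISSING))
    return out


def quality_pass(v: AnnotatedVariant, calls: Sequence[GenotypeCall], cfg: FilterConfig) -> bool:
    """Site-level quality verdict.

    True iff the Phred site quality clears the single-strand threshold,
    or the both-strands threshold when the alternate was observed on both
    strands. Per-call GQ/depth handling happens in
    :func:`degrade_low_quality_calls`, not here.
    """
    if v.site_qual >= cfg.min_site_qual_single_strand:
        return True
    return v.both_strands and v.site_qual >= cfg.min_site_qual_both_strands


def consequence_pass(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """True iff the variant's region and consequence class are retained."""
    return v.region in cfg.allowed_regions and v.consequence in cfg.allowed_consequences


def rarity_pass(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """True iff every *present* population frequency is <= max_maf.

    A variant with no frequency annotation at all is novel ("unknown")
    and passes; absent is distinct from zero.
    """
    return all(freq <= cfg.max_maf for freq in v.pop_freqs.values())


def deleterious_pass(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """False only when SIFT and PolyPhen-2 both predict benign.

    SIFT > 0.05 is benign; PolyPhen < 0.5 is benign. Variants missing
    either score pass (the prediction tools score no indels).
    """
    if not cfg.require_deleterious:
        return True
    sift_benign = v.sift is not None and v.sift > cfg.sift_deleterious_max
    polyphen_benign = v.polyphen is not None and v.polyphen < cfg.polyphen_deleterious_min
    return not (sift_benign and polyphen_benign)


def run_cascade(matrix: GenotypeMatrix, cfg: FilterConfig | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full cascade; return the surviving matrix and a report.

    Stage order is quality -> consequence -> rarity -> deleterious. The
    input matrix is not modified; surviving variants carry quality-
    degraded calls.
    """
    if cfg is None:
        cfg = FilterConfig()
    if matrix.n_variants == 0:
        raise ValidationError("cannot run the filter cascade on an empty matrix")

    degraded = [degrade_low_quality_calls(row, cfg) for row in matrix.calls]

    predicates = {
        "quality": lambda i: quality_pass(matrix.variants[i], degraded[i], cfg),
        "consequence": lambda i: consequence_pass(matrix.variants[i], cfg),
        "rarity": lambda i: rarity_pass(matrix.variants[i], cfg),
        "deleterious": lambda i: deleterious_pass(matrix.variants[i], cfg),
    }
    surviving = list(range(matrix.n_variants))
    stage_counts: list[StageCount] = []
    for stage in STAGES:
        n_in = len(surviving)
        surviving = [i for i in surviving if predicates[stage](i)]
        stage_counts.append(StageCount(stage=stage, n_in=n_in, n_removed=n_in - len(surviving), n_out=len(surviving)))
        logger.info("filter stage %-12s in=%-6d removed=%-6d out=%d", stage, n_in, n_in - len(surviving), len(surviving))

    filtered = GenotypeMatrix(
        variants=[matrix.variants[i] for i in surviving],
        samples=list(matrix.samples),
        calls=[degraded[i] for i in surviving],
    )
    report = FilterReport(stages=stage_counts, passed=[matrix.variants[i].key for i in surviving])
    return filtered, report


def first_failing_stage(v: AnnotatedVariant, calls: Sequence[GenotypeCall], cfg: FilterConfig) -> str | None:
    """Name of the first cascade stage the variant fails, or None."""
    degraded = degrade_low_quality_calls(calls, cfg)
    if not quality_pass(v, degraded, cfg):
        return "quality"
    if not consequence_pass(v, cfg):
        return "consequence"
    if not rarity_pass(v, cfg):
        return "rarity"
    if not deleterious_pass(v, cfg):
        return "deleterious"
    return None


__all__ = [
    "FilterConfig",
    "FilterReport",
    "StageCount",
    "STAGES",
    "quality_pass",
    "consequence_pass",
    "rarity_pass",
    "deleterious_pass",
    "degrade_low_quality_calls",
    "run_cascade",
    "first_failing_stage",
]
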