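"""Core data model for family-based rare-variant analysis.

All coordinates follow the VCF convention: 1-based, inclusive. Genotypes
are diploid and unphased; the four-value code distinguishes homozygous
reference (00), heterozygous (01), homozygous alternate (11) and missing.
Absent annotations are represented as ``None`` and are semantically
distinct from zero (a variant with no population-frequency record is
*novel*, not frequency-0-confirmed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping


class FamvarError(Exception):
    """Base class for all package errors."""


class ParseError(FamvarError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(FamvarError):
    """Input violated a structural precondition."""


_ALLELE_CHARS = frozenset("ACGT")


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    MNV = "MNV"


class Region(str, Enum):
    EXONIC = "exonic"
    UTR3 = "UTR3"
    UTR5 = "UTR5"
    SPLICE = "splice"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    UNKNOWN = "unknown"


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    UTR = "utr"
    OTHER = "other"
    UNKNOWN = "unknown"


class Genotype(str, Enum):
    """Diploid genotype code for one biallelic variant."""

    HOM_REF = "00"
    HET = "01"
    HOM_ALT = "11"
    MISSING = "--"

    @property
    def alt_count(self) -> int | None:
        """Number of alternate alleles carried, or None when missing."""
        return {"00": 0, "01": 1, "11": 2, "--": None}[self.value]


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then shared prefix from a ref/alt pair.

    Keeps at least one base on each side (VCF anchor-base convention),
    adjusting ``pos`` when leading bases are removed. Makes variant
    identity well-defined when the same indel is reported with different
    amounts of padding.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def classify_alleles(ref: str, alt: str) -> VariantClass:
    """Derive the variant class from normalized ref/alt lengths."""
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(alt) > len(ref):
        return VariantClass.INSERTION
    if len(alt) < len(ref):
        return VariantClass.DELETION
    return VariantClass.MNV


@dataclass(frozen=True)
class AnnotatedVariant:
    """One normalized biallelic variant with its annotations.

    ``pop_freqs`` maps a frequency-source name (e.g. ``"exac"``,
    ``"gmaf"``) to an alternate-allele fraction; sources with no record
    are simply absent from the map. ``sift`` close to 0 and ``polyphen``
    close to 1 both indicate a damaging prediction.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    region: Region = Region.UNKNOWN
    consequence: Consequence = Consequence.UNKNOWN
    dbsnp_id: str | None = None
    pop_freqs: Mapping[str, float] = field(default_factory=dict)
    sift: float | None = None
    polyphen: float | None = None
    site_qual: float = 0.0
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or set(allele) - _ALLELE_CHARS:
                raise ValidationError(f"{name} allele {allele!r} is not a non-empty ACGT string")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        for source, freq in self.pop_freqs.items():
            if not 0.0 <= freq <= 1.0:
                raise ValidationError(f"pop_freqs[{source!r}] = {freq} outside [0, 1]")
        for name, score in (("sift", self.sift), ("polyphen", self.polyphen)):
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValidationError(f"{name} score {score} outside [0, 1]")
        if self.site_qual < 0:
            raise ValidationError(f"site_qual must be >= 0, got {self.site_qual}")
        # freeze the mapping so the dataclass is safely hashable-by-key
        object.__setattr__(self, "pop_freqs", dict(self.pop_freqs))

    @property
    def variant_class(self) -> VariantClass:
        return classify_alleles(self.ref, self.alt)

    @property
    def key(self) -> str:
        """Stable identifier ``chrom:pos:ref>alt``."""
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedVariant):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and self.pos == other.pos
            and self.ref == other.ref
            and self.alt == other.alt
            and self.gene == other.gene
            and self.region == other.region
            and self.consequence == other.consequence
            and self.dbsnp_id == other.dbsnp_id
            and dict(self.pop_freqs) == dict(other.pop_freqs)
            and self.sift == other.sift
            and self.polyphen == other.polyphen
            and self.site_qual == other.site_qual
            and self.both_strands == other.both_strands
        )

    def __hash__(self) -> int:
        return hash((self.chrom, self.pos, self.ref, self.alt))


AUTOSOMES = frozenset(str(i) for i in range(1, 23)) | frozenset(f"chr{i}" for i in range(1, 23))


def is_autosomal(chrom: str) -> bool:
    return chrom in AUTOSOMES


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid call at one variant, with optional quality."""

    sample_id: str
    code: Genotype
    depth: int | None = None
    gq: float | None = None

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise ValidationError(f"depth must be >= 0, got {self.depth}")
        if self.gq is not None and self.gq < 0:
            raise ValidationError(f"gq must be >= 0, got {self.gq}")


@dataclass
class GenotypeMatrix:
    """Per-sample diploid genotype calls over an ordered variant set.

    ``calls[i][j]`` is the call for ``variants[i]`` in ``samples[j]``;
    sample order matches the source VCF header order.
    """

    variants: list[AnnotatedVariant]
    samples: list[str]
    calls: list[list[GenotypeCall]]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise ValidationError(f"duplicate sample id(s): {', '.join(dupes)}")
        if len(self.calls) != len(self.variants):
            raise ValidationError("calls row count does not match variant count")
        for i, row in enumerate(self.calls):
            if len(row) != len(self.samples):
                raise ValidationError(f"call row {i} has {len(row)} entries for {len(self.samples)} samples")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise ValidationError(f"sample {sample_id!r} not in matrix") from None

    def call(self, variant_index: int, sample_id: str) -> GenotypeCall:
        return self.calls[variant_index][self.sample_index(sample_id)]

    def genotypes(self, variant_index: int) -> dict[str, Genotype]:
        """Map sample id -> genotype code at one variant."""
        return {s: c.code for s, c in zip(self.samples, self.calls[variant_index])}

    def subset_variants(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            variants=[self.variants[i] for i in idx],
            samples=list(self.samples),
            calls=[list(self.calls[i]) for i in idx],
        )

    def with_call(self, variant_index: int, sample_id: str, call: GenotypeCall) -> None:
        self.calls[variant_index][self.sample_index(sample_id)] = call


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PedMember:
    sample_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    family_id: str = "FAM1"


@dataclass
class Pedigree:
    """A family: members with parental links, sex and affection status."""

    members: list[PedMember]

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate individual id in pedigree")
        by_id = {m.sample_id: m for m in self.members}
        for m in self.members:
            for parent_id, wanted in ((m.father_id, Sex.FEMALE), (m.mother_id, Sex.MALE)):
                if parent_id is None:
                    continue
                parent = by_id.get(parent_id)
                if parent is None:
                    raise ValidationError(
                        f"parent {parent_id!r} of {m.sample_id!r} is not defined in the pedigree"
                    )
                if parent.sex is wanted:  # wanted is the *incompatible* sex
                    raise ValidationError(
                        f"parent {parent_id!r} of {m.sample_id!r} has incompatible sex {parent.sex.value}"
                    )
        self._check_acyclic(by_id)

    def _check_acyclic(self, by_id: dict[str, PedMember]) -> None:
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        def visit(sid: str, stack: list[str]) -> None:
            if state.get(sid) == 1:
                return
            if state.get(sid) == 0:
                raise ValidationError(f"cyclic parentage involving {sid!r}")
            state[sid] = 0
            m = by_id[sid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid, stack + [sid])
            state[sid] = 1

        for sid in by_id:
            visit(sid, [])

    def member(self, sample_id: str) -> PedMember:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise ValidationError(f"no pedigree member {sample_id!r}")

    @property
    def affected_ids(self) -> list[str]:
        return [m.sample_id for m in self.members if m.affection is Affection.AFFECTED]

    @property
    def unaffected_ids(self) -> list[str]:
        return [m.sample_id for m in self.members if m.affection is Affection.UNAFFECTED]

    def parents_of(self, sample_id: str) -> list[str]:
        m = self.member(sample_id)
        return [p for p in (m.father_id, m.mother_id) if p is not None]

    @property
    def founder_ids(self) -> list[str]:
        return [m.sample_id for m in self.members if m.father_id is None and m.mother_id is None]


@dataclass(frozen=True)
class GenotypeCountTable:
    """Case/control genotype counts at one biallelic locus."""

    n00_ctrl: int
    n01_ctrl: int
    n11_ctrl: int
    n00_case: int
    n01_case: int
    n11_case: int

    def __post_init__(self) -> None:
        for name in ("n00_ctrl", "n01_ctrl", "n11_ctrl", "n00_case", "n01_case", "n11_case"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_ctrl(self) -> int:
        return self.n00_ctrl + self.n01_ctrl + self.n11_ctrl

    @property
    def n_case(self) -> int:
        return self.n00_case + self.n01_case + self.n11_case

    def controls(self) -> tuple[int, int, int]:
        return (self.n00_ctrl, self.n01_ctrl, self.n11_ctrl)

    def cases(self) -> tuple[int, int, int]:
        return (self.n00_case, self.n01_case, self.n11_case)

    def allele_counts(self, group: str) -> tuple[int, int]:
        """(wild-type, mutant) chromosome counts for ``group``."""
        n00, n01, n11 = self.controls() if group == "control" else self.cases()
        return (2 * n00 + n01, 2 * n11 + n01)


__all__ = [
    "FamvarError",
    "ParseError",
    "ValidationError",
    "VariantClass",
    "Region",
    "Consequence",
    "Genotype",
    "normalize_alleles",
    "classify_alleles",
    "AnnotatedVariant",
    "GenotypeCall",
    "GenotypeMatrix",
    "Sex",
    "Affection",
    "PedMember",
    "Pedigree",
    "GenotypeCountTable",
    "is_autosomal",
    "AUTOSOMES",
    "replace",
]
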