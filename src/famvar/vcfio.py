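"""Readers and writers for the pipeline's on-disk formats.

VCF v4.2 (multi-sample, read through pysam) is decomposed into one
:class:`~famvar.types.AnnotatedVariant` per (site, alternate allele), with
indel alleles trimmed of shared padding so that variant identity is
well-defined. PED files follow the 6-column PLINK dialect. Genotype count
tables are TSV with a ``group  n00  n01  n11`` header.

Annotation INFO keys are configurable; the defaults match the headers
this package itself writes (GENE, CSQ, REGION, EXAC_AF, GMAF, SIFT,
POLYPHEN, BOTH_STRANDS), with the rsID taken from the ID column.
Absent INFO keys yield absent fields — never defaults.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import pandas as pd
import pysam

from .types import (
    Affection,
    AnnotatedVariant,
    Consequence,
    Genotype,
    GenotypeCall,
    GenotypeCountTable,
    GenotypeMatrix,
    ParseError,
    PedMember,
    Pedigree,
    Region,
    Sex,
    ValidationError,
    normalize_alleles,
)

DEFAULT_ANNOTATION_KEYS: dict[str, str] = {
    "gene": "GENE",
    "region": "REGION",
    "consequence": "CSQ",
    "sift": "SIFT",
    "polyphen": "POLYPHEN",
    "both_strands": "BOTH_STRANDS",
}
#: INFO keys holding per-ALT population allele frequencies (Number=A)
DEFAULT_FREQ_KEYS: dict[str, str] = {"exac": "EXAC_AF", "gmaf": "GMAF"}


def _sig6(x: float) -> float:
    """Quantize a float to 6 significant digits.

    htslib stores INFO floats in single precision; quantizing on both the
    write and read path makes VCF round-trips exact for annotation values.
    """
    return float(format(float(x), ".6g"))


def _prescan_vcf(path: Path) -> None:
    """Cheap structural validation with line numbers before pysam parses."""
    n_cols_expected: int | None = None
    saw_chrom_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 8:
                    raise ParseError(f"{path}: line {lineno}: truncated #CHROM header")
                samples = cols[9:]
                if len(set(samples)) != len(samples):
                    dupes = sorted({s for s in samples if samples.count(s) > 1})
                    raise ValidationError(f"{path}: duplicate sample id(s): {', '.join(dupes)}")
                n_cols_expected = len(cols)
                saw_chrom_header = True
                continue
            if line.startswith("#"):
                continue
            if not saw_chrom_header:
                raise ParseError(f"{path}: line {lineno}: data line before #CHROM header")
            cols = line.split("\t")
            if n_cols_expected is not None and len(cols) != n_cols_expected:
                raise ParseError(
                    f"{path}: line {lineno}: {len(cols)} columns, expected {n_cols_expected}"
                )
            if not cols[1].isdigit():
                raise ParseError(f"{path}: line {lineno}: POS {cols[1]!r} is not a positive integer")
    if not saw_chrom_header:
        raise ParseError(f"{path}: no #CHROM header line found")


def _info_scalar(record: "pysam.VariantRecord", key: str, alt_index: int):
    """Fetch an INFO value, unpacking per-ALT tuples to this alternate."""
    if key not in record.info:
        return None
    value = record.info[key]
    if isinstance(value, tuple):
        value = value[alt_index] if alt_index < len(value) else None
    return value


def _decode_gt(gt: tuple | None, alt_allele_index: int, n_alts: int) -> Genotype:
    """Recode a raw diploid GT tuple against one decomposed alternate."""
    if gt is None or len(gt) == 0 or all(a is None for a in gt):
        return Genotype.MISSING
    if any(a is None for a in gt):
        return Genotype.MISSING
    if len(gt) != 2:
        raise ValidationError(f"non-diploid genotype {gt!r}: autosomal diploid calls required")
    for allele in gt:
        if allele > n_alts:
            raise ValidationError(f"genotype allele index {allele} exceeds ALT count {n_alts}")
    n = sum(1 for allele in gt if allele == alt_allele_index)
    return {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}[n]


def read_vcf(
    path: str | Path,
    annotation_keys: Mapping[str, str] | None = None,
    freq_keys: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multiallelic sites are decomposed into one biallelic record per
    alternate allele; a sample's genotype for each decomposed record is
    its count of that allele (so ``1/2`` is HET for both alternates).
    Symbolic alternates (``<DEL>``, ``*``) are skipped.
    """
    path = Path(path)
    keys = dict(DEFAULT_ANNOTATION_KEYS, **(annotation_keys or {}))
    fkeys = dict(freq_keys if freq_keys is not None else DEFAULT_FREQ_KEYS)
    _prescan_vcf(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: malformed VCF header: {exc}") from exc
    samples = list(vf.header.samples)
    variants: list[AnnotatedVariant] = []
    calls: list[list[GenotypeCall]] = []
    for record in vf:
        alts = record.alts or ()
        for alt_index, alt in enumerate(alts):
            if alt is None or set(alt.upper()) - set("ACGT"):
                continue  # symbolic / spanning-deletion alternates
            pos, ref, alt_n = normalize_alleles(record.pos, record.ref, alt)

            def _get(field: str):
                return _info_scalar(record, keys[field], alt_index)

            pop_freqs: dict[str, float] = {}
            for source, info_key in fkeys.items():
                value = _info_scalar(record, info_key, alt_index)
                if value is not None:
                    pop_freqs[source] = _sig6(value)
            region_raw = _get("region")
            consequence_raw = _get("consequence")
            sift = _get("sift")
            polyphen = _get("polyphen")
            variant = AnnotatedVariant(
                chrom=record.chrom,
                pos=pos,
                ref=ref,
                alt=alt_n,
                gene=_get("gene"),
                region=Region(region_raw) if region_raw is not None else Region.UNKNOWN,
                consequence=(
                    Consequence(consequence_raw) if consequence_raw is not None else Consequence.UNKNOWN
                ),
                dbsnp_id=record.id,
                pop_freqs=pop_freqs,
                sift=_sig6(sift) if sift is not None else None,
                polyphen=_sig6(polyphen) if polyphen is not None else None,
                site_qual=_sig6(record.qual) if record.qual is not None else 0.0,
                both_strands=keys["both_strands"] in record.info,
            )
            row: list[GenotypeCall] = []
            for sample_id in samples:
                s = record.samples[sample_id]
                code = _decode_gt(s.get("GT"), alt_index + 1, len(alts))
                depth = s.get("DP")
                gq = s.get("GQ")
                row.append(
                    GenotypeCall(
                        sample_id=sample_id,
                        code=code,
                        depth=int(depth) if depth is not None else None,
                        gq=float(gq) if gq is not None else None,
                    )
                )
            variants.append(variant)
            calls.append(row)
    vf.close()
    return GenotypeMatrix(variants=variants, samples=samples, calls=calls)


_VCF_HEADER_LINES = [
    '##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">',
    '##INFO=<ID=REGION,Number=A,Type=String,Description="Genomic region class">',
    '##INFO=<ID=CSQ,Number=A,Type=String,Description="Consequence class">',
    '##INFO=<ID=EXAC_AF,Number=A,Type=Float,Description="ExAC alternate allele frequency">',
    '##INFO=<ID=GMAF,Number=A,Type=Float,Description="1000 Genomes global minor allele frequency">',
    '##INFO=<ID=SIFT,Number=A,Type=Float,Description="SIFT score (damaging near 0)">',
    '##INFO=<ID=POLYPHEN,Number=A,Type=Float,Description="PolyPhen-2 score (damaging near 1)">',
    '##INFO=<ID=BOTH_STRANDS,Number=0,Type=Flag,Description="Alternate observed on both strands">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
]

_GT_STRINGS = {Genotype.HOM_REF: "0/0", Genotype.HET: "0/1", Genotype.HOM_ALT: "1/1", Genotype.MISSING: "./."}


def _fmt_float(x: float) -> str:
    s = format(_sig6(x), ".6g")
    return s


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> Path:
    """Write a GenotypeMatrix as an uncompressed biallelic VCF v4.2."""
    path = Path(path)
    chroms: list[str] = []
    for v in matrix.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += _VCF_HEADER_LINES
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples)
        if matrix.samples
        else "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    )
    for v, row in zip(matrix.variants, matrix.calls):
        info_parts: list[str] = []
        if v.gene is not None:
            info_parts.append(f"GENE={v.gene}")
        if v.region is not Region.UNKNOWN:
            info_parts.append(f"REGION={v.region.value}")
        if v.consequence is not Consequence.UNKNOWN:
            info_parts.append(f"CSQ={v.consequence.value}")
        if "exac" in v.pop_freqs:
            info_parts.append(f"EXAC_AF={_fmt_float(v.pop_freqs['exac'])}")
        if "gmaf" in v.pop_freqs:
            info_parts.append(f"GMAF={_fmt_float(v.pop_freqs['gmaf'])}")
        if v.sift is not None:
            info_parts.append(f"SIFT={_fmt_float(v.sift)}")
        if v.polyphen is not None:
            info_parts.append(f"POLYPHEN={_fmt_float(v.polyphen)}")
        if v.both_strands:
            info_parts.append("BOTH_STRANDS")
        info = ";".join(info_parts) if info_parts else "."
        fields = [
            v.chrom,
            str(v.pos),
            v.dbsnp_id or ".",
            v.ref,
            v.alt,
            _fmt_float(v.site_qual),
            "PASS",
            info,
            "GT:DP:GQ",
        ]
        for call in row:
            dp = str(call.depth) if call.depth is not None else "."
            gq = format(int(call.gq)) if call.gq is not None else "."
            fields.append(f"{_GT_STRINGS[call.code]}:{dp}:{gq}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


_SEX_FROM_PED = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_SEX_TO_PED = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_FROM_PED = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED, "0": Affection.UNKNOWN, "-9": Affection.UNKNOWN}
_AFF_TO_PED = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2", Affection.UNKNOWN: "0"}


def read_ped(path: str | Path) -> Pedigree:
    """Read a 6-column whitespace-delimited PED file (PLINK dialect)."""
    path = Path(path)
    members: list[PedMember] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 columns, got {len(cols)}")
            fam, sid, father, mother, sex, pheno = cols
            if sex not in _SEX_FROM_PED:
                raise ParseError(f"{path}: line {lineno}: sex code {sex!r} not in {{0,1,2}}")
            if pheno not in _AFF_FROM_PED:
                raise ParseError(f"{path}: line {lineno}: phenotype code {pheno!r} not in {{0,1,2,-9}}")
            members.append(
                PedMember(
                    sample_id=sid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_FROM_PED[sex],
                    affection=_AFF_FROM_PED[pheno],
                    family_id=fam,
                )
            )
    return Pedigree(members=members)


def write_ped(pedigree: Pedigree, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for m in pedigree.members:
        rows.append(
            "\t".join(
                [
                    m.family_id,
                    m.sample_id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    _SEX_TO_PED[m.sex],
                    _AFF_TO_PED[m.affection],
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n")
    return path


_GROUP_ALIASES = {"control": "control", "controls": "control", "ctrl": "control", "case": "case", "cases": "case"}


def read_count_table(path: str | Path) -> GenotypeCountTable:
    """Read a case/control genotype count table.

    Expects TSV with header columns ``group n00 n01 n11`` and one row per
    group (control, case); extra columns (e.g. percentages) are ignored.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: could not parse count table: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = ["group", "n00", "n01", "n11"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    counts: dict[str, tuple[int, int, int]] = {}
    for _, row in df.iterrows():
        group = _GROUP_ALIASES.get(str(row["group"]).strip().lower())
        if group is None:
            raise ValidationError(f"{path}: unknown group label {row['group']!r}")
        triple = []
        for col in ("n00", "n01", "n11"):
            value = row[col]
            fval = float(value)
            if not math.isfinite(fval) or fval < 0 or fval != int(fval):
                raise ValidationError(f"{path}: {col} for {group} must be a non-negative integer, got {value!r}")
            triple.append(int(fval))
        counts[group] = tuple(triple)  # type: ignore[assignment]
    for group in ("control", "case"):
        if group not in counts:
            raise ValidationError(f"{path}: no row for group {group!r}")
    (c00, c01, c11), (a00, a01, a11) = counts["control"], counts["case"]
    return GenotypeCountTable(
        n00_ctrl=c00, n01_ctrl=c01, n11_ctrl=c11, n00_case=a00, n01_case=a01, n11_case=a11
    )


def write_count_table(table: GenotypeCountTable, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "group\tn00\tn01\tn11",
        f"control\t{table.n00_ctrl}\t{table.n01_ctrl}\t{table.n11_ctrl}",
        f"case\t{table.n00_case}\t{table.n01_case}\t{table.n11_case}",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


__all__ = [
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_count_table",
    "write_count_table",
    "DEFAULT_ANNOTATION_KEYS",
    "DEFAULT_FREQ_KEYS",
]
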