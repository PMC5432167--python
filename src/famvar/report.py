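"""Rendering of association panels and segregation screens.

The association report mirrors the shape of a standard genotype/allele
distribution table: a reference genotype row, codominant rows, the
collapsed-model rows and the allelic rows, with percentages computed
from the supplied counts. Display rounding is half-up at fixed per-row
precision; the JSON rendering keeps full double precision and is the
machine-readable source of truth.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal

from .assoc import AssociationPanel, CONTRAST_LABELS
from .segregation import SegregationResult
from .types import GenotypeCountTable, ValidationError

#: decimal places used for the chi2 / OR columns, per contrast row
_CHI2_DECIMALS = {
    "het_vs_ref": 2,
    "hom_vs_ref": 3,
    "dominant": 2,
    "overdominant": 2,
    "recessive": 3,
    "allelic": 2,
}
_OR_DECIMALS = {
    "het_vs_ref": 2,
    "hom_vs_ref": 2,
    "dominant": 2,
    "overdominant": 3,
    "recessive": 2,
    "allelic": 2,
}


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (2.5 -> 3), unlike float banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(x: float, decimals: int) -> str:
    return f"{round_half_up(x, decimals):.{decimals}f}"


def _pct(count: int, total: int) -> str:
    return f"{count} ({100 * count / total:.2f})" if total else f"{count} (-)"


def render_association_tsv(panel: AssociationPanel) -> str:
    """Seven-row genotype/allele distribution report as TSV text."""
    if not panel.results:
        raise ValidationError("empty association panel; nothing to render")
    t: GenotypeCountTable = panel.table
    n_ctrl, n_case = t.n_ctrl, t.n_case
    (ctrl_wt, ctrl_mut), (case_wt, case_mut) = t.allele_counts("control"), t.allele_counts("case")
    lines = ["genotype_or_allele\tcontrol (%)\tcases (%)\tchi2\tp\tOR (95% CI)"]
    lines.append(f"00\t{_pct(t.n00_ctrl, n_ctrl)}\t{_pct(t.n00_case, n_case)}\treference\t\t")

    def row(label: str, contrast: str, ctrl_cell: str, case_cell: str) -> str:
        r = panel.result(contrast)
        chi2 = _fmt(r.chi2, _CHI2_DECIMALS[contrast])
        orr = _fmt(r.or_point, _OR_DECIMALS[contrast])
        lo = _fmt(r.ci_low, 2)
        hi = _fmt(r.ci_high, 2)
        p = f"{r.p:.4g}"
        return f"{label}\t{ctrl_cell}\t{case_cell}\t{chi2}\t{p}\t{orr} ({lo}-{hi})"

    lines.append(row("01", "het_vs_ref", _pct(t.n01_ctrl, n_ctrl), _pct(t.n01_case, n_case)))
    lines.append(row("11", "hom_vs_ref", _pct(t.n11_ctrl, n_ctrl), _pct(t.n11_case, n_case)))
    lines.append(
        row(
            "00 vs 01+11",
            "dominant",
            f"{t.n00_ctrl} vs {t.n01_ctrl + t.n11_ctrl}",
            f"{t.n00_case} vs {t.n01_case + t.n11_case}",
        )
    )
    lines.append(
        row(
            "01 vs 00+11",
            "overdominant",
            f"{t.n01_ctrl} vs {t.n00_ctrl + t.n11_ctrl}",
            f"{t.n01_case} vs {t.n00_case + t.n11_case}",
        )
    )
    lines.append(
        row(
            "11 vs 00+01",
            "recessive",
            f"{t.n11_ctrl} vs {t.n00_ctrl + t.n01_ctrl}",
            f"{t.n11_case} vs {t.n00_case + t.n01_case}",
        )
    )
    lines.append(f"allele 0\t{_pct(ctrl_wt, 2 * n_ctrl)}\t{_pct(case_wt, 2 * n_case)}\treference\t\t")
    lines.append(row("allele 1", "allelic", _pct(ctrl_mut, 2 * n_ctrl), _pct(case_mut, 2 * n_case)))
    return "\n".join(lines) + "\n"


def panel_to_dict(panel: AssociationPanel) -> dict:
    """Full-precision machine-readable form of an association panel."""
    return {
        "counts": {
            "control": list(panel.table.controls()),
            "case": list(panel.table.cases()),
        },
        "contrasts": [
            {
                "contrast": r.contrast,
                "comparison": CONTRAST_LABELS[r.contrast],
                "table": {"a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d},
                "exposed": r.table.exposure_label,
                "chi2": r.chi2,
                "df": r.df,
                "p": r.p,
                "or": r.or_point,
                "ci95": [r.ci_low, r.ci_high],
                "method_notes": r.method_notes,
            }
            for r in panel.results
        ],
        "hwe": {
            group: {
                "allele_freq": h.allele_freq,
                "expected": list(h.expected),
                "chi2": h.chi2,
                "df": h.df,
                "p": h.p,
            }
            for group, h in panel.hwe.items()
        },
    }


def render_association_json(panel: AssociationPanel) -> str:
    return json.dumps(panel_to_dict(panel), indent=2)


def render_segregation_tsv(results: list[SegregationResult]) -> str:
    """One row per AR hit / CH pair with per-sample genotype evidence."""
    lines = ["model\tgene\tvariants\tverdict\tgenotypes"]
    for r in results:
        variant_keys = ",".join(v.key for v in r.variants)
        if r.model == "AR":
            evidence = ";".join(f"{sid}={g.value}" for sid, g in sorted(r.evidence.items()))
        else:
            parts = []
            for v, g in zip(r.variants, r.evidence):
                parts.append(v.key + ":" + ",".join(f"{sid}={code.value}" for sid, code in sorted(g.items())))
            evidence = "|".join(parts)
        gene = r.variants[0].gene or "."
        lines.append(f"{r.model}\t{gene}\t{variant_keys}\t{r.verdict}\t{evidence}")
    return "\n".join(lines) + "\n"


__all__ = [
    "render_association_tsv",
    "render_association_json",
    "render_segregation_tsv",
    "panel_to_dict",
    "round_half_up",
]
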