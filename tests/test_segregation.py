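"""AR / compound-het segregation verdicts against brute-force oracles."""

import itertools

import numpy as np
import pytest

from famvar import (
    AnnotatedVariant,
    Consequence,
    Genotype,
    GenotypeCall,
    GenotypeMatrix,
    Region,
    ValidationError,
)
from famvar.segregation import (
    CONSISTENT,
    INCONSISTENT,
    INDETERMINATE,
    ar_consistent,
    ch_candidates,
    screen_family,
)
from famvar.simulate import study_pedigree

MEMBERS5 = ["III-1", "III-2", "IV-1", "IV-3", "IV-4"]  # father, mother, sib, affected x2
G = Genotype


def build_matrix(genotype_rows, gene="G1", chrom="1"):
    """One variant per row; genotype_rows are dicts sample -> Genotype."""
    variants, calls = [], []
    for i, row in enumerate(genotype_rows):
        variants.append(
            AnnotatedVariant(
                chrom=chrom, pos=1000 + i, ref="A", alt="G" if i % 2 == 0 else "C", gene=gene,
                region=Region.EXONIC, consequence=Consequence.MISSENSE, site_qual=60.0,
            )
        )
        calls.append([GenotypeCall(s, row[s], 50, 90.0) for s in MEMBERS5])
    return GenotypeMatrix(variants=variants, samples=list(MEMBERS5), calls=calls)


def genotypes(father, mother, sib, aff1, aff2):
    return dict(zip(MEMBERS5, (father, mother, sib, aff1, aff2)))


@pytest.fixture
def ped5():
    return study_pedigree(sequenced_only=True)


def ar_oracle(father, mother, sib, aff1, aff2):
    """Independent truth: affected HOM_ALT, parents HET, sib not HOM_ALT."""
    return (
        aff1 is G.HOM_ALT
        and aff2 is G.HOM_ALT
        and father is G.HET
        and mother is G.HET
        and sib is not G.HOM_ALT
    )


class TestArConsistent:
    def test_canonical_ar_pattern(self, ped5):
        m = build_matrix([genotypes(G.HET, G.HET, G.HET, G.HOM_ALT, G.HOM_ALT)])
        assert ar_consistent(0, m, ped5).verdict == CONSISTENT

    def test_all_hom_ref_inconsistent(self, ped5):
        m = build_matrix([genotypes(*([G.HOM_REF] * 5))])
        assert ar_consistent(0, m, ped5).verdict == INCONSISTENT

    def test_hom_alt_parent_inconsistent(self, ped5):
        """A homozygous-alt parent would be affected under full penetrance."""
        m = build_matrix([genotypes(G.HOM_ALT, G.HET, G.HOM_REF, G.HOM_ALT, G.HOM_ALT)])
        assert ar_consistent(0, m, ped5).verdict == INCONSISTENT

    def test_exhaustive_enumeration_matches_oracle(self, ped5):
        """All 3^5 non-missing assignments agree with the brute-force oracle."""
        n_consistent = 0
        for combo in itertools.product([G.HOM_REF, G.HET, G.HOM_ALT], repeat=5):
            m = build_matrix([genotypes(*combo)])
            verdict = ar_consistent(0, m, ped5).verdict
            expected = CONSISTENT if ar_oracle(*combo) else INCONSISTENT
            assert verdict == expected, combo
            n_consistent += verdict == CONSISTENT
        # oracle count: sib free over {HOM_REF, HET}, everyone else pinned
        assert n_consistent == 2

    def test_missing_policy(self, ped5):
        row = genotypes(G.HET, G.MISSING, G.HET, G.HOM_ALT, G.HOM_ALT)
        m = build_matrix([row])
        assert ar_consistent(0, m, ped5, missing_policy="strict").verdict == INDETERMINATE
        assert ar_consistent(0, m, ped5, missing_policy="permissive").verdict == CONSISTENT

    def test_missing_does_not_mask_definite_violation(self, ped5):
        row = genotypes(G.HET, G.MISSING, G.HET, G.HOM_REF, G.HOM_ALT)
        m = build_matrix([row])
        assert ar_consistent(0, m, ped5, missing_policy="strict").verdict == INCONSISTENT


def ch_pair_oracle(g1, g2, ped):
    """Brute-force compound-het truth by enumerating allele origins.

    For each variant the affected child's single alternate allele may
    originate from any heterozygous parent. The pair is consistent when
    every feasible origin assignment is trans (and the basic carrier
    checks hold), indeterminate when trans and cis are both feasible.
    """
    affected = ped.affected_ids
    father, mother = ped.parents_of(affected[0])
    for sid in affected:
        if g1[sid] is not G.HET or g2[sid] is not G.HET:
            return INCONSISTENT
    if G.HOM_ALT in (g1[father], g1[mother], g2[father], g2[mother]):
        return INCONSISTENT
    feasible = []
    for o1, o2 in itertools.product((father, mother), repeat=2):
        if g1[o1] is G.HET and g2[o2] is G.HET:
            feasible.append(o1 != o2)
    if not feasible or not any(feasible):
        return INCONSISTENT
    if not all(feasible):
        return INDETERMINATE
    for sid in ped.unaffected_ids:
        if sid not in g1:
            continue
        if g1[sid] in (G.HET, G.HOM_ALT) and g2[sid] in (G.HET, G.HOM_ALT):
            return INCONSISTENT
    return CONSISTENT


class TestChCandidates:
    def test_canonical_trans_pair(self, ped5):
        m = build_matrix(
            [
                genotypes(G.HET, G.HOM_REF, G.HET, G.HET, G.HET),  # paternal allele
                genotypes(G.HOM_REF, G.HET, G.HOM_REF, G.HET, G.HET),  # maternal allele
            ]
        )
        results = ch_candidates("G1", m, ped5)
        assert len(results) == 1 and results[0].verdict == CONSISTENT

    def test_cis_configuration_rejected(self, ped5):
        """Both alleles inherited from the father only: no pair."""
        m = build_matrix(
            [
                genotypes(G.HET, G.HOM_REF, G.HOM_REF, G.HET, G.HET),
                genotypes(G.HET, G.HOM_REF, G.HOM_REF, G.HET, G.HET),
            ]
        )
        assert ch_candidates("G1", m, ped5) == []

    def test_double_het_parents_ambiguous(self, ped5):
        """Both parents carry both variants: phase unresolvable, not consistent."""
        m = build_matrix(
            [
                genotypes(G.HET, G.HET, G.HOM_REF, G.HET, G.HET),
                genotypes(G.HET, G.HET, G.HOM_REF, G.HET, G.HET),
            ]
        )
        results = ch_candidates("G1", m, ped5)
        assert [r.verdict for r in results] == [INDETERMINATE]

    def test_carrier_sibling_excludes_pair(self, ped5):
        """An unaffected sib heterozygous for both alleles breaks the model."""
        m = build_matrix(
            [
                genotypes(G.HET, G.HOM_REF, G.HET, G.HET, G.HET),
                genotypes(G.HOM_REF, G.HET, G.HET, G.HET, G.HET),
            ]
        )
        assert ch_candidates("G1", m, ped5) == []

    def test_single_variant_gene_yields_empty_list(self, ped5):
        m = build_matrix([genotypes(G.HET, G.HOM_REF, G.HET, G.HET, G.HET)])
        assert ch_candidates("G1", m, ped5) == []

    def test_random_configurations_match_oracle(self, ped5):
        """All pairs over 4 variants/gene, 300 random genotype settings."""
        rng = np.random.default_rng(2024)
        codes = [G.HOM_REF, G.HET, G.HOM_ALT]
        for _ in range(300):
            rows = [
                genotypes(*(codes[i] for i in rng.integers(0, 3, size=5)))
                for _ in range(4)
            ]
            m = build_matrix(rows)
            got = {
                frozenset(v.key for v in r.variants): r.verdict
                for r in ch_candidates("G1", m, ped5)
            }
            for i, j in itertools.combinations(range(4), 2):
                expected = ch_pair_oracle(rows[i], rows[j], ped5)
                key = frozenset((m.variants[i].key, m.variants[j].key))
                if expected == INCONSISTENT:
                    assert key not in got
                else:
                    assert got.get(key) == expected, (rows[i], rows[j])


class TestScreenFamily:
    def test_no_affected_member_rejected(self):
        healthy = study_pedigree()
        members = [m for m in healthy.members]
        from famvar.types import Pedigree, PedMember, Affection
        import dataclasses

        unaffected = Pedigree(
            members=[dataclasses.replace(m, affection=Affection.UNAFFECTED) for m in members]
        )
        m = build_matrix([genotypes(G.HET, G.HET, G.HET, G.HOM_ALT, G.HOM_ALT)])
        with pytest.raises(ValidationError, match="no affected"):
            screen_family(m, unaffected)

    def test_eight_ar_variant_fixture_recovered(self, ped5):
        """A matrix shaped like the discovery set (8 AR-segregating variants
        across 8 genes, sib HET or HOM_REF) yields exactly 8 AR results."""
        rows, genes = [], []
        for i in range(8):
            sib = G.HET if i % 2 == 0 else G.HOM_REF
            rows.append(genotypes(G.HET, G.HET, sib, G.HOM_ALT, G.HOM_ALT))
            genes.append(f"GENE{i}")
        variants, calls = [], []
        for i, row in enumerate(rows):
            variants.append(
                AnnotatedVariant(
                    chrom=str(i + 1), pos=5000 + i, ref="C", alt="T", gene=genes[i],
                    region=Region.EXONIC, consequence=Consequence.MISSENSE, site_qual=80.0,
                )
            )
            calls.append([GenotypeCall(s, row[s], 50, 90.0) for s in MEMBERS5])
        m = GenotypeMatrix(variants=variants, samples=list(MEMBERS5), calls=calls)
        results = screen_family(m, ped5)
        assert len(results) == 8 and all(r.model == "AR" for r in results)

    def test_non_autosomal_variants_excluded(self, ped5):
        m = build_matrix([genotypes(G.HET, G.HET, G.HET, G.HOM_ALT, G.HOM_ALT)], chrom="X")
        assert screen_family(m, ped5) == []

    def test_verdicts_invariant_under_reordering(self, ped5):
        rows = [
            genotypes(G.HET, G.HET, G.HOM_REF, G.HOM_ALT, G.HOM_ALT),
            genotypes(G.HET, G.HOM_REF, G.HET, G.HET, G.HET),
            genotypes(G.HOM_REF, G.HET, G.HOM_REF, G.HET, G.HET),
        ]
        m = build_matrix(rows)
        base = [(r.model, tuple(v.key for v in r.variants)) for r in screen_family(m, ped5)]
        # reverse variant order
        m_rev = GenotypeMatrix(
            variants=list(reversed(m.variants)), samples=m.samples, calls=list(reversed(m.calls))
        )
        rev = [(r.model, tuple(v.key for v in r.variants)) for r in screen_family(m_rev, ped5)]
        assert base == rev
        # permute sample order
        order = [3, 1, 4, 0, 2]
        m_perm = GenotypeMatrix(
            variants=m.variants,
            samples=[m.samples[i] for i in order],
            calls=[[row[i] for i in order] for row in m.calls],
        )
        perm = [(r.model, tuple(v.key for v in r.variants)) for r in screen_family(m_perm, ped5)]
        assert base == perm

    def test_extra_unaffected_member_only_shrinks_consistent_set(self, ped5):
        """Adding a genotyped unaffected sibling can only remove candidates."""
        rows = [
            genotypes(G.HET, G.HET, G.HOM_REF, G.HOM_ALT, G.HOM_ALT),
            genotypes(G.HET, G.HET, G.HET, G.HOM_ALT, G.HOM_ALT),
        ]
        m5 = build_matrix(rows)
        base_keys = {v.key for r in screen_family(m5, ped5) for v in r.variants}
        ped7 = study_pedigree()
        extra = ["IV-2", "IV-5"]
        variants = m5.variants
        for extra_geno in itertools.product([G.HOM_REF, G.HET, G.HOM_ALT], repeat=2):
            calls = []
            for row in m5.calls:
                calls.append(list(row) + [GenotypeCall(s, g, 50, 90.0) for s, g in zip(extra, extra_geno)])
            m7 = GenotypeMatrix(variants=variants, samples=MEMBERS5 + extra, calls=calls)
            keys = {v.key for r in screen_family(m7, ped7) for v in r.variants}
            assert keys <= base_keys
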