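"""VCF / PED / count-table reading, normalization and round-trips."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famvar import (
    AnnotatedVariant,
    Consequence,
    Genotype,
    GenotypeCall,
    GenotypeMatrix,
    ParseError,
    PedMember,
    Pedigree,
    Region,
    Sex,
    Affection,
    ValidationError,
    VariantClass,
    read_count_table,
    read_ped,
    read_vcf,
    write_count_table,
    write_ped,
    write_vcf,
)
from famvar.types import classify_alleles, normalize_alleles


class TestReadVcf:
    def test_basic_genotype_recoding(self, vcf_factory):
        path = vcf_factory(
            ["1\t100\t.\tA\tG\t50\tPASS\tGENE=G1;REGION=exonic;CSQ=missense\tGT:DP:GQ\t0/0:40:80\t0/1:40:80\t1/1:40:80"],
            ["s1", "s2", "s3"],
        )
        m = read_vcf(path)
        assert m.n_variants == 1 and m.samples == ["s1", "s2", "s3"]
        assert [c.code for c in m.calls[0]] == [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT]
        v = m.variants[0]
        assert v.gene == "G1" and v.region is Region.EXONIC and v.consequence is Consequence.MISSENSE
        assert v.site_qual == 50.0

    def test_multiallelic_decomposition_conserves_allele_counts(self, vcf_factory):
        """Every diploid GT over 2 ALTs decomposes with allele-count conservation."""
        gt_pairs = list(itertools.combinations_with_replacement([0, 1, 2], 2))
        samples = [f"s{i}" for i in range(len(gt_pairs))]
        gts = "\t".join(f"{a}/{b}:40:80" for a, b in gt_pairs)
        path = vcf_factory([f"1\t500\t.\tC\tA,T\t60\tPASS\t.\tGT:DP:GQ\t{gts}"], samples)
        m = read_vcf(path)
        assert m.n_variants == 2
        assert {v.alt for v in m.variants} == {"A", "T"}
        for j, (a, b) in enumerate(gt_pairs):
            raw_alt_total = sum(1 for x in (a, b) if x != 0)
            decomposed_total = sum(m.calls[i][j].code.alt_count for i in range(2))
            assert decomposed_total == raw_alt_total
            # per-allele count as well
            for i, v in enumerate(m.variants):
                allele_index = 1 if v.alt == "A" else 2
                assert m.calls[i][j].code.alt_count == sum(1 for x in (a, b) if x == allele_index)

    def test_insertion_classified(self, vcf_factory):
        """An anchored 3-bp insertion (ref T, alt TATT) is class `insertion`."""
        path = vcf_factory(
            ["1\t77558664\trs76976178\tT\tTATT\t75\tPASS\tGENE=AK5;REGION=exonic;CSQ=inframe_indel;BOTH_STRANDS\tGT:DP:GQ\t0/1:50:90"],
            ["s1"],
        )
        v = read_vcf(path).variants[0]
        assert v.variant_class is VariantClass.INSERTION
        assert v.dbsnp_id == "rs76976178"
        assert v.both_strands

    def test_absent_info_yields_absent_fields(self, vcf_factory):
        path = vcf_factory(["1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP:GQ\t0/1:40:80"], ["s1"])
        v = read_vcf(path).variants[0]
        assert v.gene is None and v.sift is None and v.polyphen is None
        assert v.pop_freqs == {} and not v.both_strands
        assert v.region is Region.UNKNOWN and v.consequence is Consequence.UNKNOWN

    def test_malformed_body_line_names_line_number(self, vcf_factory):
        path = vcf_factory(["1\tnotanumber\t.\tA\tG\t50\tPASS\t.\tGT:DP:GQ\t0/1:40:80"], ["s1"])
        with pytest.raises(ParseError, match=r"line 18"):  # first body line of the fixture
            read_vcf(path)

    def test_duplicate_sample_rejected(self, vcf_factory):
        path = vcf_factory(["1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP:GQ\t0/1:40:80\t0/0:40:80"], ["s1", "s1"])
        with pytest.raises(ValidationError, match="duplicate sample"):
            read_vcf(path)

    def test_haploid_call_rejected(self, vcf_factory):
        path = vcf_factory(["1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP:GQ\t1:40:80"], ["s1"])
        with pytest.raises(ValidationError, match="diploid"):
            read_vcf(path)

    def test_missing_genotype(self, vcf_factory):
        path = vcf_factory(["1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP:GQ\t./.:.:."], ["s1"])
        m = read_vcf(path)
        call = m.calls[0][0]
        assert call.code is Genotype.MISSING and call.depth is None and call.gq is None


class TestNormalization:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (100, "T", "TATT", (100, "T", "TATT")),  # anchored insertion kept
            (100, "CTCC", "C", (100, "CTCC", "C")),  # anchored deletion kept
            (100, "ATG", "ATC", (102, "G", "C")),  # shared prefix trimmed
            (100, "GAT", "CAT", (100, "G", "C")),  # shared suffix trimmed
            (100, "TAAA", "TA", (100, "TAA", "T")),  # suffix first, anchor kept
        ],
    )
    def test_trimming(self, pos, ref, alt, expected):
        assert normalize_alleles(pos, ref, alt) == expected

    @given(
        pos=st.integers(1, 10**6),
        ref=st.text(alphabet="ACGT", min_size=1, max_size=6),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=6),
    )
    @settings(max_examples=200, derandomize=True)
    def test_normalization_idempotent_and_classifiable(self, pos, ref, alt):
        if ref == alt:
            return
        npos, nref, nalt = normalize_alleles(pos, ref, alt)
        assert normalize_alleles(npos, nref, nalt) == (npos, nref, nalt)
        assert nref and nalt
        cls = classify_alleles(nref, nalt)
        if len(nref) == len(nalt) == 1:
            assert cls is VariantClass.SNV
        elif len(nalt) > len(nref):
            assert cls is VariantClass.INSERTION
        elif len(nalt) < len(nref):
            assert cls is VariantClass.DELETION


class TestRoundTrips:
    def test_vcf_round_trip(self, tmp_path):
        variants = [
            AnnotatedVariant(
                chrom="1", pos=77558664, ref="T", alt="TATT", gene="AK5",
                region=Region.EXONIC, consequence=Consequence.INFRAME_INDEL,
                dbsnp_id="rs76976178", pop_freqs={}, site_qual=75.0, both_strands=True,
            ),
            AnnotatedVariant(
                chrom="9", pos=96051100, ref="C", alt="T", gene="WNK2",
                region=Region.EXONIC, consequence=Consequence.MISSENSE,
                pop_freqs={"gmaf": 0.0044}, sift=0.02, polyphen=0.98, site_qual=44.0,
            ),
        ]
        calls = [
            [GenotypeCall("s1", Genotype.HET, 50, 90.0), GenotypeCall("s2", Genotype.HOM_ALT, 45, 85.0)],
            [GenotypeCall("s1", Genotype.HOM_REF, 60, 99.0), GenotypeCall("s2", Genotype.MISSING)],
        ]
        m = GenotypeMatrix(variants=variants, samples=["s1", "s2"], calls=calls)
        path = write_vcf(m, tmp_path / "rt.vcf")
        m2 = read_vcf(path)
        assert m2.samples == m.samples
        assert m2.variants == m.variants
        assert m2.calls == m.calls

    def test_ped_round_trip(self, tmp_path, family7):
        path = write_ped(family7, tmp_path / "fam.ped")
        ped2 = read_ped(path)
        assert ped2 == family7

    def test_count_table_round_trip(self, tmp_path, ak5_counts):
        path = write_count_table(ak5_counts, tmp_path / "counts.tsv")
        assert read_count_table(path) == ak5_counts


class TestReadPed:
    def test_study_family(self, tmp_path):
        lines = [
            "FAM1 III-1 0 0 1 1",
            "FAM1 III-2 0 0 2 1",
            "FAM1 IV-1 III-1 III-2 1 1",
            "FAM1 IV-2 III-1 III-2 2 1",
            "FAM1 IV-3 III-1 III-2 2 2",
            "FAM1 IV-4 III-1 III-2 2 2",
            "FAM1 IV-5 III-1 III-2 1 0",
        ]
        path = tmp_path / "fam.ped"
        path.write_text("\n".join(lines) + "\n")
        ped = read_ped(path)
        assert len(ped.members) == 7
        assert ped.affected_ids == ["IV-3", "IV-4"]
        assert ped.member("IV-5").affection is Affection.UNKNOWN
        assert ped.parents_of("IV-3") == ["III-1", "III-2"]

    def test_single_founder(self, tmp_path):
        path = tmp_path / "one.ped"
        path.write_text("F1 A 0 0 1 2\n")
        ped = read_ped(path)
        assert len(ped.members) == 1 and ped.founder_ids == ["A"]

    def test_undefined_parent_rejected(self, tmp_path):
        path = tmp_path / "bad.ped"
        path.write_text("F1 kid GHOST 0 1 2\n")
        with pytest.raises(ValidationError, match="GHOST"):
            read_ped(path)

    def test_cyclic_parentage_rejected(self):
        with pytest.raises(ValidationError, match="cyclic"):
            Pedigree(
                members=[
                    PedMember("a", father_id="b", sex=Sex.MALE),
                    PedMember("b", father_id="a", sex=Sex.MALE),
                ]
            )

    def test_incompatible_parent_sex_rejected(self):
        with pytest.raises(ValidationError, match="incompatible sex"):
            Pedigree(
                members=[
                    PedMember("mom", sex=Sex.FEMALE),
                    PedMember("kid", father_id="mom", sex=Sex.MALE),
                ]
            )


class TestReadCountTable:
    def test_ak5_cohort_counts(self, tmp_path):
        path = tmp_path / "t3.tsv"
        path.write_text(
            "group\tn00\tn01\tn11\tpct00\n"
            "control\t20\t35\t45\t19.56\n"
            "case\t42\t26\t32\t42.55\n"
        )
        t = read_count_table(path)
        assert t.controls() == (20, 35, 45) and t.cases() == (42, 26, 32)
        assert t.allele_counts("control") == (75, 125)
        assert t.allele_counts("case") == (110, 90)

    def test_all_zero_rows_parse(self, tmp_path):
        path = tmp_path / "z.tsv"
        path.write_text("group\tn00\tn01\tn11\ncontrol\t0\t0\t0\ncase\t0\t0\t0\n")
        t = read_count_table(path)
        assert t.n_ctrl == 0  # rejected later by test preconditions, not here

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("group\tn00\tn01\ncontrol\t20\t35\ncase\t42\t26\n")
        with pytest.raises(ParseError, match="n11"):
            read_count_table(path)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "n.tsv"
        path.write_text("group\tn00\tn01\tn11\ncontrol\t-1\t35\t45\ncase\t42\t26\t32\n")
        with pytest.raises(ValidationError):
            read_count_table(path)

    def test_non_integer_count_rejected(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text("group\tn00\tn01\tn11\ncontrol\t20.5\t35\t45\ncase\t42\t26\t32\n")
        with pytest.raises(ValidationError):
            read_count_table(path)
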