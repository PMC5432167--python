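import pytest

from famvar import ak5_cohort_counts
from famvar.simulate import study_pedigree

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=2>
##contig=<ID=9>
##contig=<ID=chr1>
##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">
##INFO=<ID=REGION,Number=A,Type=String,Description="Region">
##INFO=<ID=CSQ,Number=A,Type=String,Description="Consequence">
##INFO=<ID=EXAC_AF,Number=A,Type=Float,Description="ExAC AF">
##INFO=<ID=GMAF,Number=A,Type=Float,Description="Global MAF">
##INFO=<ID=SIFT,Number=A,Type=Float,Description="SIFT">
##INFO=<ID=POLYPHEN,Number=A,Type=Float,Description="PolyPhen">
##INFO=<ID=BOTH_STRANDS,Number=0,Type=Flag,Description="Both strands">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def make_vcf(tmp_path, body_lines, samples, name="test.vcf"):
    """Write a minimal VCF with the standard test header."""
    path = tmp_path / name
    header = VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
    path.write_text(header + "".join(line + "\n" for line in body_lines))
    return path


@pytest.fixture
def ak5_counts():
    return ak5_cohort_counts()


@pytest.fixture
def family5():
    """The five exome-sequenced members: parents, two affected, one healthy sib."""
    return study_pedigree(sequenced_only=True)


@pytest.fixture
def family7():
    return study_pedigree()


@pytest.fixture
def vcf_factory(tmp_path):
    def _make(body_lines, samples, name="test.vcf"):
        return make_vcf(tmp_path, body_lines, samples, name)

    return _make
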