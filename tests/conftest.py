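import numpy as np
import pytest

from pgxdiff.types import SamplePanel, VariantRecord


@pytest.fixture
def toy_panel() -> SamplePanel:
    return SamplePanel([
        ("s1", "POPA", None),
        ("s2", "POPA", None),
        ("s3", "POPA", None),
        ("s4", "POPB", None),
        ("s5", "POPB", None),
    ])


@pytest.fixture
def toy_vcf(tmp_path):
    """Five-sample VCF: a biallelic SNP, a multi-allelic SNP and an indel."""
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=1>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4\ts5",
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\t./.",
            "1\t200\trs2\tA\tC,T\t.\tPASS\t.\tGT\t0/1\t1/1\t0/2\t2/2\t1/2",
            "1\t300\trs3\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0\t0/0",
        ]
    )
    path = tmp_path / "toy.vcf"
    path.write_text(text + "\n")
    return path


def make_variant(chrom="1", pos=100, rsid="rsX", ref="A", alt="G", genotypes=(0, 1, 2)):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        rsid=rsid,
        ref=ref,
        alt=alt,
        genotypes=np.asarray(genotypes, dtype=np.int8),
    )
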