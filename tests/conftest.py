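import textwrap

import pytest

from crossase import POP_A, POP_B
from crossase.io_formats.vcf import VariantSite

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=100000>
    ##contig=<ID=chr2,length=100000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta1\ta2\tb1\tb2
    """
)

POP_MAP = {"a1": POP_A, "a2": POP_A, "b1": POP_B, "b2": POP_B}


def write_vcf_text(path, rows, header=VCF_HEADER):
    path.write_text(header + "".join(r + "\n" for r in rows))
    return str(path)


def make_site(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    qual=50.0,
    genotypes=None,
    populations=None,
):
    """Small VariantSite helper: genotypes/populations default to two
    samples per parental line."""
    if genotypes is None:
        genotypes = {"a1": (0, 0), "a2": (0, 0), "b1": (1, 1), "b2": (1, 1)}
    if populations is None:
        populations = {k: POP_MAP.get(k, POP_A) for k in genotypes}
    return VariantSite(
        chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
        genotypes=genotypes, populations=populations,
    )


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"


def write_sam_text(path, rows, header=SAM_HEADER):
    path.write_text(header + "".join(r + "\n" for r in rows))
    return str(path)


def sam_line(qname="r1", flag=0, chrom="chr1", pos=100, mapq=60, cigar="10M",
             seq="ACGTACGTAC", qual=None):
    if qual is None:
        qual = "I" * len(seq)
    return "\t".join(
        [qname, str(flag), chrom, str(pos), str(mapq), cigar, "*", "0", "0", seq, qual]
    )


@pytest.fixture
def tiny_config():
    """Small, fast simulation config (~1 s end to end)."""
    from crossase.synthetic_data import default_config

    return default_config(
        seed=11,
        n_chrom=1,
        chrom_len=2_000_000,
        n_sites=2_000,
        n_genes=6,
        window_size=100_000,
        step=50_000,
        sweep_windows=[("chr1", 1_000_000, 1_100_000, POP_A)],
        tissues=("liver", "bone"),
        depth_mean=80.0,
    )
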