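"""Shared fixtures: tiny hand-written VCF/GTF texts and simulated tables."""

from __future__ import annotations

import pandas as pd
import pytest

import bulkseq as bq

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##contig=<ID=chr2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tHIGH\tLOW
"""


def make_vcf(tmp_path, body: str, name: str = "fixture.vcf", header: str = VCF_HEADER):
    path = tmp_path / name
    path.write_text(header + body)
    return path


@pytest.fixture
def three_site_vcf(tmp_path):
    """Two biallelic SNPs plus one indel (the indel must be skipped)."""
    body = (
        "chr1\t100\t.\tA\tT\t50\t.\t.\tGT:AD:DP:GQ\t1/1:0,15:15:90\t0/1:8,7:15:80\n"
        "chr1\t200\t.\tG\tGA\t50\t.\t.\tGT:AD:DP:GQ\t0/1:5,5:10:60\t0/1:5,5:10:60\n"
        "chr1\t300\t.\tC\tG\t50\t.\t.\tGT:AD:DP:GQ\t0/1:12,8:22:70\t0/0:18,2:20:65\n"
    )
    return make_vcf(tmp_path, body)


@pytest.fixture
def toy_gtf(tmp_path):
    """Two explicit genes plus one exon-only gene spanning 100-900 on chr2."""
    lines = [
        'chr1\ttest\tgene\t1000\t2000\t.\t+\t.\tgene_id "geneA";',
        'chr1\ttest\tgene\t5000\t7500\t.\t-\t.\tgene_id "geneB";',
        'chr2\ttest\texon\t100\t400\t.\t+\t.\tgene_id "geneC"; transcript_id "geneC.t1";',
        'chr2\ttest\texon\t700\t900\t.\t+\t.\tgene_id "geneC"; transcript_id "geneC.t1";',
    ]
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def small_sim():
    """A small simulated F2 experiment used by several modules."""
    return bq.simulate_bulks(
        bq.SimConfig(
            chrom_lengths=(("chr1", 10_000_000), ("chr2", 10_000_000)),
            n_snps_per_chrom=200,
            causal=("chr1", 5_000_000),
            seed=11,
        )
    )


def make_track(pos, raw, chrom="chr1", stat="g") -> pd.DataFrame:
    return pd.DataFrame({"CHROM": chrom, "POS": pos, "STAT": stat, "RAW": raw})
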