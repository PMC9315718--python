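"""Two-bulk segregant simulator with known ground truth.

Emulates the allele-depth data produced by sequencing two bulks of
phenotypically extreme individuals drawn from an F2 or RIL mapping
population with (optionally) one causal locus.  Physical distance maps to
recombination fraction through the Haldane function with a uniform
recombination rate, bulk composition is sampled binomially from the
design expectations, and read counts are binomial given composition with
Poisson (optionally gamma-overdispersed) depth.  The generator is the
package's test bed: every downstream module is exercised on its output
without any external data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .snptable import SNP_COLUMNS, empty_snp_table, sort_snp_table, validate_snp_table

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study design of a simulated two-bulk experiment.

    Attributes
    ----------
    chrom_lengths : [(name, bp), ...] of the simulated chromosomes.
    n_snps_per_chrom : SNP count per chromosome (positions uniform).
    causal : (chrom, pos) of the single causal locus, or None for a null
        genome.
    design : "F2" (selection acts on individuals of an F2 cross) or "RIL"
        (bulks are pools of near-homozygous recombinant inbred lines).
    n_high, n_low : individuals (F2) or lines (RIL) per bulk.
    mean_depth : expected reads per SNP per bulk (Poisson).
    depth_dispersion : optional gamma-Poisson overdispersion; depth
        variance becomes mean + mean²/dispersion.  None = pure Poisson.
    gq_low_fraction : fraction of SNPs assigned sub-threshold GQ (< 20)
        in both bulks, for exercising GQ filters.
    low_bulk : "unselected" (low bulk drawn at random from the
        population) or "contrasted" (low bulk selected homozygous for
        the reference allele, mirroring the high bulk).
    recomb_rate : cM per Mb (uniform; Haldane map function).
    seed : RNG seed; fixed seed gives bit-identical output.
    """

    chrom_lengths: Sequence[tuple[str, int]] = (("chr1", 50_000_000),)
    n_snps_per_chrom: int = 2000
    causal: tuple[str, int] | None = ("chr1", 25_000_000)
    design: str = "F2"
    n_high: int = 30
    n_low: int = 30
    mean_depth: float = 50.0
    depth_dispersion: float | None = None
    gq_low_fraction: float = 0.0
    low_bulk: str = "unselected"
    recomb_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps_per_chrom < 1:
            raise ValueError("need at least one SNP per chromosome")
        if self.n_high < 1 or self.n_low < 1:
            raise ValueError("bulk sizes must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.design not in ("F2", "RIL"):
            raise ValueError(f"design must be 'F2' or 'RIL', got {self.design!r}")
        if self.low_bulk not in ("unselected", "contrasted"):
            raise ValueError(f"low_bulk must be 'unselected' or 'contrasted'")
        if not 0 <= self.gq_low_fraction <= 1:
            raise ValueError("gq_low_fraction must be in [0, 1]")
        if self.causal is not None:
            lengths = dict(self.chrom_lengths)
            chrom, pos = self.causal
            if chrom not in lengths or not 1 <= pos <= lengths[chrom]:
                raise ValueError(f"causal locus {self.causal} outside the genome")


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    causal: tuple[str, int] | None
    design: str
    n_high: int
    n_low: int
    #: expected alt-chromosome frequency at the causal SNP per bulk
    causal_freq_high: float
    causal_freq_low: float
    #: per-SNP expectations: CHROM POS EXP_FREQ_HIGH EXP_FREQ_LOW
    expected_freqs: pd.DataFrame = field(repr=False, default=None)


def haldane_recomb_fraction(distance_bp, recomb_rate: float):
    """Recombination fraction r = (1 − exp(−2d/100))/2, d in cM via recomb_rate (cM/Mb)."""
    d_cm = np.asarray(distance_bp, dtype=float) / 1e6 * recomb_rate
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def _expected_freqs(cfg: SimConfig, chrom: str, pos: np.ndarray):
    """Expected alt frequency per bulk as a function of position."""
    if cfg.causal is not None and chrom == cfg.causal[0]:
        r = haldane_recomb_fraction(np.abs(pos - cfg.causal[1]), cfg.recomb_rate)
    else:
        r = np.full(len(pos), 0.5)  # unlinked: 50% transmission
    if cfg.design == "F2":
        f_high = 1.0 - r
        f_low = r if cfg.low_bulk == "contrasted" else np.full(len(pos), 0.5)
    else:  # RIL: line fixation probability via R = 2r/(1+2r)
        big_r = 2.0 * r / (1.0 + 2.0 * r)
        f_high = 1.0 - big_r
        f_low = big_r if cfg.low_bulk == "contrasted" else np.full(len(pos), 0.5)
    return f_high, f_low


def _sample_depth(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    if cfg.depth_dispersion is None:
        return rng.poisson(cfg.mean_depth, size=n)
    lam = rng.gamma(cfg.depth_dispersion, cfg.mean_depth / cfg.depth_dispersion, size=n)
    return rng.poisson(lam)


def simulate_bulks(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a two-bulk SNP table and its ground truth.

    Sampling hierarchy per SNP and bulk: the bulk's alt composition m is
    Binomial(2n, f) chromosomes (F2) or Binomial(n, f) homozygous lines
    (RIL) at the design frequency f for that position; alt reads are then
    Binomial(depth, m/(2n)) (F2) or Binomial(depth, m/n) (RIL).
    """
    rng = np.random.default_rng(cfg.seed)
    frames = []
    truth_frames = []
    for chrom, length in cfg.chrom_lengths:
        pos = rng.integers(1, length + 1, size=cfg.n_snps_per_chrom)
        if cfg.causal is not None and chrom == cfg.causal[0]:
            # the causal variant itself segregates between the parents,
            # so it appears in the marker set
            pos[0] = cfg.causal[1]
        pos = np.unique(pos)
        n = len(pos)
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        f_high, f_low = _expected_freqs(cfg, chrom, pos)

        record = {"CHROM": chrom, "POS": pos}
        for bulk, f, n_ind in (("HIGH", f_high, cfg.n_high), ("LOW", f_low, cfg.n_low)):
            chroms_per = 2 * n_ind if cfg.design == "F2" else n_ind
            m = rng.binomial(chroms_per, f)
            depth = _sample_depth(rng, cfg, n)
            alt_reads = rng.binomial(depth, m / chroms_per)
            record[f"AD_REF.{bulk}"] = depth - alt_reads
            record[f"AD_ALT.{bulk}"] = alt_reads
            record[f"DP.{bulk}"] = depth
            gq = rng.integers(60, 100, size=n)
            if cfg.gq_low_fraction > 0:
                n_low_gq = int(round(cfg.gq_low_fraction * n))
                low_idx = rng.choice(n, size=n_low_gq, replace=False)
                gq[low_idx] = rng.integers(0, 20, size=n_low_gq)
            record[f"GQ.{bulk}"] = gq

        df = pd.DataFrame(record)
        df["REF"] = _BASES[ref_idx]
        df["ALT"] = _BASES[alt_idx]
        frames.append(df[SNP_COLUMNS])
        truth_frames.append(
            pd.DataFrame(
                {"CHROM": chrom, "POS": pos, "EXP_FREQ_HIGH": f_high, "EXP_FREQ_LOW": f_low}
            )
        )

    table = sort_snp_table(pd.concat(frames, ignore_index=True)) if frames else empty_snp_table()
    validate_snp_table(table)
    expected = pd.concat(truth_frames, ignore_index=True).sort_values(
        ["CHROM", "POS"], kind="mergesort", ignore_index=True
    )
    if cfg.causal is None:
        freq_hi = freq_lo = 0.5
    else:
        fh, fl = _expected_freqs(cfg, cfg.causal[0], np.array([cfg.causal[1]]))
        freq_hi, freq_lo = float(fh[0]), float(fl[0])
    truth = SimTruth(
        causal=cfg.causal,
        design=cfg.design,
        n_high=cfg.n_high,
        n_low=cfg.n_low,
        causal_freq_high=freq_hi,
        causal_freq_low=freq_lo,
        expected_freqs=expected,
    )
    return table, truth


def _genotype(ref: int, alt: int) -> str:
    total = ref + alt
    if total == 0:
        return "./."
    frac = alt / total
    if frac >= 0.9:
        return "1/1"
    if frac <= 0.1:
        return "0/0"
    return "0/1"


def write_fixture_vcf(table: pd.DataFrame, truth: SimTruth | None, sink) -> None:
    """Write a SnpTable as a two-sample (HIGH, LOW) VCF 4.2 fixture.

    Ground truth, when given, is stored in a ``##bulkseq_truth`` header
    meta-line so it survives the round trip; genotypes are majority
    calls from the allele depths.  ``read_vcf_bulks`` recovers the table
    exactly (sites with zero depth in a bulk come back as missing).
    """
    validate_snp_table(table)
    lines = ["##fileformat=VCFv4.2", "##source=bulkseq-simulate"]
    if truth is not None and truth.causal is not None:
        lines.append(
            "##bulkseq_truth=<causal_chrom={},causal_pos={},design={},n_high={},n_low={}>".format(
                truth.causal[0], truth.causal[1], truth.design, truth.n_high, truth.n_low
            )
        )
    for chrom in pd.unique(table["CHROM"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tHIGH\tLOW",
    ]
    for row in table[SNP_COLUMNS].itertuples(index=False, name=None):
        r = dict(zip(SNP_COLUMNS, row))
        samples = []
        for bulk in ("HIGH", "LOW"):
            ref, alt = r[f"AD_REF.{bulk}"], r[f"AD_ALT.{bulk}"]
            samples.append(
                f"{_genotype(ref, alt)}:{ref},{alt}:{r[f'DP.{bulk}']}:{r[f'GQ.{bulk}']}"
            )
        lines.append(
            "\t".join(
                [
                    str(r["CHROM"]),
                    str(r["POS"]),
                    ".",
                    str(r["REF"]),
                    str(r["ALT"]),
                    ".",
                    ".",
                    ".",
                    "GT:AD:DP:GQ",
                    samples[0],
                    samples[1],
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)


_TRUTH_RE = re.compile(
    r"##bulkseq_truth=<causal_chrom=([^,>]+),causal_pos=(\d+),design=([^,>]+),"
    r"n_high=(\d+),n_low=(\d+)>"
)


def read_fixture_truth(vcf_path) -> dict | None:
    """Parse the ``##bulkseq_truth`` meta-line of a fixture VCF, if present."""
    with open(vcf_path) as fh:
        for line in fh:
            if not line.startswith("##"):
                return None
            m = _TRUTH_RE.match(line.strip())
            if m:
                return {
                    "causal_chrom": m.group(1),
                    "causal_pos": int(m.group(2)),
                    "design": m.group(3),
                    "n_high": int(m.group(4)),
                    "n_low": int(m.group(5)),
                }
    return None
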