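"""Candidate-region calling from smoothed, thresholded statistic tracks.

A SNP is significant when its smoothed statistic exceeds an empirical
quantile threshold or its permutation p-value falls below a cutoff.
Maximal runs of significant SNPs on one chromosome become candidate
regions; nearby runs are merged and sparse ones discarded.  Region
bounds are the first and last significant SNP positions, so lengths are
``(end − start)/1e6`` Mb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smooth import ThresholdSpec, quantile_threshold

REGION_COLUMNS = ["CHROM", "START", "END", "LENGTH_MB", "N_SNPS", "PEAK_POS", "PEAK_VALUE"]


@dataclass(frozen=True)
class CandidateRegion:
    """A run of significant SNPs: chrom, bp bounds, Mb length and peak."""

    chrom: str
    start: int
    end: int
    length_mb: float
    n_snps: int
    peak_pos: int
    peak_value: float


def call_candidate_regions(
    track: pd.DataFrame,
    spec: ThresholdSpec,
    merge_gap: float,
    min_snps: int = 10,
    absolute: bool | None = None,
) -> list[CandidateRegion]:
    """Call candidate regions on a smoothed track.

    Parameters
    ----------
    track : statistic track with SMOOTHED filled (and PVALUE filled when
        ``spec.mode == "pvalue"``).
    spec : significance criterion; in quantile mode the threshold is the
        empirical quantile of the observed smoothed values themselves.
    merge_gap : adjacent significant runs separated by <= this many bp
        are merged into one region.
    min_snps : regions carrying fewer significant SNPs are discarded.
    absolute : compare ``|smoothed|`` against a threshold computed on
        ``|smoothed|`` (the default for signed statistics: ``None``
        auto-enables this when any smoothed value is negative).

    Raising the quantile (or lowering alpha) yields regions nested inside
    those of the looser threshold.
    """
    if "SMOOTHED" not in track.columns:
        raise ValueError("track has no SMOOTHED column; run tricube_smooth first")
    track = track.reset_index(drop=True)
    smoothed = track["SMOOTHED"].to_numpy(dtype=float)
    if absolute is None:
        absolute = bool(np.any(smoothed < 0))
    values = np.abs(smoothed) if absolute else smoothed

    if spec.mode == "quantile":
        threshold = quantile_threshold(values[np.isfinite(values)], spec.quantile)
        significant = values >= threshold
    else:
        if "PVALUE" not in track.columns or track["PVALUE"].isna().any():
            raise ValueError("pvalue mode requires a PVALUE column; run permutation_pvalues")
        significant = track["PVALUE"].to_numpy(dtype=float) <= spec.alpha

    regions: list[CandidateRegion] = []
    for chrom, grp in track.groupby("CHROM", sort=False):
        idx = grp.index.to_numpy()
        sig_idx = idx[significant[idx]]
        if sig_idx.size == 0:
            continue
        pos = track["POS"].to_numpy()
        # split significant SNPs into runs whose consecutive gaps exceed merge_gap
        gaps = np.diff(pos[sig_idx])
        breaks = np.flatnonzero(gaps > merge_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [sig_idx.size - 1]])
        for a, b in zip(starts, ends):
            members = sig_idx[a : b + 1]
            if members.size < min_snps:
                continue
            peak_local = members[np.argmax(values[members])]
            regions.append(
                CandidateRegion(
                    chrom=str(chrom),
                    start=int(pos[members[0]]),
                    end=int(pos[members[-1]]),
                    length_mb=(float(pos[members[-1]]) - float(pos[members[0]])) / 1e6,
                    n_snps=int(members.size),
                    peak_pos=int(pos[peak_local]),
                    peak_value=float(smoothed[peak_local]),
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Tabulate regions with columns CHROM START END LENGTH_MB N_SNPS PEAK_POS PEAK_VALUE."""
    return pd.DataFrame(
        [
            (r.chrom, r.start, r.end, r.length_mb, r.n_snps, r.peak_pos, r.peak_value)
            for r in regions
        ],
        columns=REGION_COLUMNS,
    )


def write_regions_bed(regions: list[CandidateRegion], sink) -> None:
    """Write regions as BED (0-based half-open; conversion done here)."""
    df = pd.DataFrame(
        [(r.chrom, r.start - 1, r.end, f"region_{i + 1}") for i, r in enumerate(regions)]
    )
    df.to_csv(sink, sep="\t", index=False, header=False)
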