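"""Canonical two-bulk SNP table.

A SNP table is a :class:`pandas.DataFrame` with twelve columns describing,
per biallelic SNP, the read support observed in two pooled samples
("bulks") of phenotypically extreme individuals.  The column layout follows
the GATK ``VariantsToTable`` convention: chromosome, 1-based position,
reference and alternative alleles, then allele depths (AD), total depth
(DP) and genotype quality (GQ) for the "high" bulk followed by the "low"
bulk.  "high"/"low" is positional metadata only — the statistics in
:mod:`bulkseq.stats` define their own orientation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical column order of a two-bulk SNP table.
SNP_COLUMNS = [
    "CHROM",
    "POS",
    "REF",
    "ALT",
    "AD_REF.HIGH",
    "AD_ALT.HIGH",
    "DP.HIGH",
    "GQ.HIGH",
    "AD_REF.LOW",
    "AD_ALT.LOW",
    "DP.LOW",
    "GQ.LOW",
]

_COUNT_COLUMNS = SNP_COLUMNS[4:]


def empty_snp_table() -> pd.DataFrame:
    """Return an empty SNP table with the canonical columns and dtypes."""
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in SNP_COLUMNS})
    df["POS"] = df["POS"].astype(np.int64)
    for c in _COUNT_COLUMNS:
        df[c] = df[c].astype(np.int64)
    return df


def sort_snp_table(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by (CHROM, POS) — the deterministic order used package-wide."""
    return df.sort_values(["CHROM", "POS"], kind="mergesort", ignore_index=True)


def validate_snp_table(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` if *df* violates the SNP-table invariants.

    Checked: canonical columns present; POS >= 1; all depths and GQ >= 0;
    positions strictly increasing within each chromosome; (CHROM, POS,
    REF, ALT) unique; AD_REF + AD_ALT <= DP in each bulk (AD counts only
    reads informative for the two alleles, so DP may exceed their sum).
    """
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    if len(df) == 0:
        return
    if (df["POS"] < 1).any():
        raise ValueError("POS must be >= 1")
    for c in _COUNT_COLUMNS:
        if (df[c] < 0).any():
            raise ValueError(f"negative values in column {c}")
    for chrom, grp in df.groupby("CHROM", sort=False):
        if not grp["POS"].is_monotonic_increasing:
            raise ValueError(f"positions not sorted on chromosome {chrom}")
    if df.duplicated(["CHROM", "POS", "REF", "ALT"]).any():
        raise ValueError("duplicate (CHROM, POS, REF, ALT) records")
    for b in ("HIGH", "LOW"):
        ad_sum = df[f"AD_REF.{b}"] + df[f"AD_ALT.{b}"]
        if (ad_sum > df[f"DP.{b}"]).any():
            raise ValueError(f"AD_REF + AD_ALT exceeds DP in bulk {b}")
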