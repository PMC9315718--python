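"""Read and write two-bulk SNP tables (VCF and GATK VariantsToTable TSV)."""

from __future__ import annotations

import logging
import os
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .snptable import SNP_COLUMNS, empty_snp_table, sort_snp_table, validate_snp_table

logger = logging.getLogger(__name__)

# cyvcf2 genotype codes: 0 HOM_REF, 1 HET, 2 UNKNOWN/missing, 3 HOM_ALT
_GT_UNKNOWN = 2


def read_vcf_bulks(vcf_source, high_bulk: str, low_bulk: str) -> pd.DataFrame:
    """Read a two-bulk SNP table from a multi-sample VCF.

    Keeps one record per biallelic SNP site at which *both* bulk samples
    carry a called genotype with AD present.  Indels, symbolic alleles and
    multi-allelic sites are skipped, as are sites genotyped in only one
    bulk.  Missing DP falls back to the AD sum; missing GQ becomes 0 so a
    downstream GQ filter can remove the record.

    Parameters
    ----------
    vcf_source : path
        VCF 4.x file whose header declares FORMAT fields AD, DP and GQ.
    high_bulk, low_bulk : str
        Sample names of the two bulks.
    """
    vcf = VCF(str(vcf_source))
    try:
        samples = list(vcf.samples)
        for name in (high_bulk, low_bulk):
            if name not in samples:
                raise ValueError(
                    f"bulk sample {name!r} not found in VCF; samples present: {samples}"
                )
        header = vcf.raw_header
        for fmt in ("AD", "DP", "GQ"):
            if f"##FORMAT=<ID={fmt}," not in header:
                raise ValueError(f"VCF header does not declare FORMAT field {fmt}")
        hi = samples.index(high_bulk)
        lo = samples.index(low_bulk)

        rows: list[tuple] = []
        n_skipped = 0
        for var in vcf:
            if not var.is_snp or len(var.ALT) != 1:
                n_skipped += 1
                continue
            gts = var.gt_types
            if gts[hi] == _GT_UNKNOWN or gts[lo] == _GT_UNKNOWN:
                n_skipped += 1
                continue
            ad = var.format("AD")
            if ad is None:
                n_skipped += 1
                continue
            ad = np.asarray(ad)
            if np.any(ad[[hi, lo], :2] < 0):  # cyvcf2 encodes missing as < 0
                n_skipped += 1
                continue
            dp = var.format("DP")
            gq = var.format("GQ")

            def _dp(i):
                if dp is None or dp[i][0] < 0:
                    return int(ad[i, 0] + ad[i, 1])
                return int(dp[i][0])

            def _gq(i):
                if gq is None:
                    return 0
                v = np.asarray(gq[i]).ravel()[0]
                return int(v) if np.isfinite(v) and v >= 0 else 0

            rows.append(
                (
                    var.CHROM,
                    var.POS,
                    var.REF,
                    var.ALT[0],
                    int(ad[hi, 0]),
                    int(ad[hi, 1]),
                    _dp(hi),
                    _gq(hi),
                    int(ad[lo, 0]),
                    int(ad[lo, 1]),
                    _dp(lo),
                    _gq(lo),
                )
            )
    finally:
        vcf.close()

    if not rows:
        logger.info("Imported 0 SNPs (%d sites skipped)", n_skipped)
        return empty_snp_table()
    df = pd.DataFrame(rows, columns=SNP_COLUMNS)
    sorted_df = sort_snp_table(df)
    if not sorted_df.equals(df):
        logger.warning("VCF records were not coordinate-sorted; output re-sorted")
        df = sorted_df
    validate_snp_table(df)
    logger.info("Imported %d SNPs (%d sites skipped)", len(df), n_skipped)
    return df


def read_gatk_table(
    tsv_source, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a two-bulk SNP table from a GATK ``VariantsToTable``-style TSV.

    By default the canonical twelve column names are expected
    (:data:`bulkseq.snptable.SNP_COLUMNS`).  ``column_map`` maps canonical
    names to the names actually present; an allele-depth pair may instead
    be supplied as one combined ``"ref,alt"`` column by mapping the key
    ``"AD.HIGH"`` (or ``"AD.LOW"``) to that column, in which case the
    split ``AD_REF``/``AD_ALT`` entries are ignored.
    """
    cmap = dict(column_map or {})
    df = pd.read_csv(tsv_source, sep="\t", dtype=str)

    out = {}
    for canon in ("CHROM", "POS", "REF", "ALT"):
        src = cmap.get(canon, canon)
        if src not in df.columns:
            raise ValueError(f"column for {canon} ({src!r}) not found in table")
        out[canon] = df[src]
    for bulk in ("HIGH", "LOW"):
        combined = cmap.get(f"AD.{bulk}")
        if combined is not None:
            if combined not in df.columns:
                raise ValueError(f"column for AD.{bulk} ({combined!r}) not found in table")
            parts = df[combined].str.split(",", expand=True)
            if parts.shape[1] < 2:
                raise ValueError(f"AD column {combined!r} is not of the form 'ref,alt'")
            out[f"AD_REF.{bulk}"] = parts[0]
            out[f"AD_ALT.{bulk}"] = parts[1]
        else:
            for side in ("AD_REF", "AD_ALT"):
                canon = f"{side}.{bulk}"
                src = cmap.get(canon, canon)
                if src not in df.columns:
                    raise ValueError(f"column for {canon} ({src!r}) not found in table")
                out[canon] = df[src]
        for field in ("DP", "GQ"):
            canon = f"{field}.{bulk}"
            src = cmap.get(canon, canon)
            if src not in df.columns:
                raise ValueError(f"column for {canon} ({src!r}) not found in table")
            out[canon] = df[src]

    result = pd.DataFrame(out)[SNP_COLUMNS]
    if len(result) == 0:
        return empty_snp_table()
    for c in ["POS"] + SNP_COLUMNS[4:]:
        parsed = pd.to_numeric(result[c], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-integer value {result[c].iloc[row]!r} in column {c}, data row {row + 1}"
            )
        result[c] = parsed.astype(np.int64)
    result = sort_snp_table(result)
    validate_snp_table(result)
    logger.info("Imported %d SNPs from table", len(result))
    return result


def write_snp_table(table: pd.DataFrame, sink) -> None:
    """Write a SNP table as a tab-delimited file with the canonical columns.

    Round-trips exactly through :func:`read_gatk_table`.
    """
    validate_snp_table(table)
    table.to_csv(sink, sep="\t", index=False, columns=SNP_COLUMNS)
    if isinstance(sink, (str, os.PathLike)):
        logger.info("Wrote %d SNPs to %s", len(table), sink)
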