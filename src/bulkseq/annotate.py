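"""Genes inside candidate regions, with optional differential-expression flags.

Once candidate regions are called, the genes they contain are the
shortlist for follow-up.  Gene extents come from a GTF annotation; a
user-supplied differential-expression table (gene id, log2 fold change,
FDR) may be joined to flag which of those genes were differentially
expressed between the contrasting samples.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, replace

import gffutils
import pandas as pd

from .regions import CandidateRegion

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["CHROM", "START", "END", "GENE", "LOG2FC", "FDR", "IS_DEG"]


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval (1-based inclusive) with optional DE attributes."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    log2fc: float | None = None
    fdr: float | None = None
    is_deg: bool | None = None


def read_gtf_genes(gtf_source) -> list[GeneRecord]:
    """Extract one record per gene from a GTF annotation.

    For GTFs without explicit ``gene`` features, a gene's extent is the
    min/max over all features sharing its ``gene_id`` (the same rule
    gives the correct span when a ``gene`` feature is present, since it
    spans its children).  Output sorted by (chrom, start).
    """
    path = os.fspath(gtf_source)
    n_features = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            n_features += 1
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 9 and "gene_id" not in parts[8]:
                raise ValueError(f"GTF line {lineno} lacks a gene_id attribute")
    if n_features == 0:
        return []

    with tempfile.TemporaryDirectory() as tmp:
        db = gffutils.create_db(
            path,
            dbfn=os.path.join(tmp, "genes.db"),
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        extents: dict[str, list] = {}
        for feat in db.all_features():
            gene_ids = feat.attributes.get("gene_id")
            if not gene_ids:
                continue
            gid = gene_ids[0]
            cur = extents.get(gid)
            if cur is None:
                extents[gid] = [feat.seqid, feat.start, feat.end, feat.strand or "."]
            else:
                if feat.seqid != cur[0]:
                    logger.warning("gene %s spans chromosomes; keeping %s", gid, cur[0])
                    continue
                cur[1] = min(cur[1], feat.start)
                cur[2] = max(cur[2], feat.end)

    genes = [
        GeneRecord(gene_id=gid, chrom=c, start=int(s), end=int(e), strand=st)
        for gid, (c, s, e, st) in extents.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    logger.info("Read %d genes from %s", len(genes), path)
    return genes


def read_deg_table(source) -> pd.DataFrame:
    """Read a differential-expression table: gene_id, log2fc, fdr (TSV).

    The first three columns are used regardless of their header names.
    """
    df = pd.read_csv(source, sep="\t")
    if df.shape[1] < 3:
        raise ValueError("DEG table needs at least three columns: gene_id, log2fc, fdr")
    df = df.iloc[:, :3]
    df.columns = ["gene_id", "log2fc", "fdr"]
    return df


def genes_in_regions(
    genes: list[GeneRecord],
    regions: list[CandidateRegion],
    deg_table: pd.DataFrame | None = None,
) -> list[GeneRecord]:
    """Genes overlapping any candidate region, optionally DEG-flagged.

    Overlap is closed-interval on the same chromosome: ``gene.start <=
    region.end and gene.end >= region.start`` — a gene touching a region
    boundary is included; strand is ignored.  When a DEG table is given,
    ``log2fc``/``fdr`` are joined by gene id and ``is_deg`` marks
    presence in the table; the join never changes the gene set.
    """
    deg: dict[str, tuple[float, float]] | None = None
    if deg_table is not None:
        if deg_table["gene_id"].duplicated().any():
            dupes = deg_table.loc[deg_table["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene_id in DEG table: {sorted(set(dupes))}")
        deg = {
            str(r.gene_id): (float(r.log2fc), float(r.fdr))
            for r in deg_table.itertuples(index=False)
        }

    by_chrom: dict[str, list[CandidateRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    hits: list[GeneRecord] = []
    for g in genes:
        if any(
            g.start <= r.end and g.end >= r.start for r in by_chrom.get(g.chrom, [])
        ):
            if deg is None:
                hits.append(g)
            elif g.gene_id in deg:
                fc, fdr = deg[g.gene_id]
                hits.append(replace(g, log2fc=fc, fdr=fdr, is_deg=True))
            else:
                hits.append(replace(g, is_deg=False))
    hits.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return hits


def annotation_to_frame(genes: list[GeneRecord]) -> pd.DataFrame:
    """Tabulate annotated genes: CHROM START END GENE LOG2FC FDR IS_DEG."""
    return pd.DataFrame(
        [
            (g.chrom, g.start, g.end, g.gene_id, g.log2fc, g.fdr, g.is_deg)
            for g in genes
        ],
        columns=ANNOTATION_COLUMNS,
    )
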