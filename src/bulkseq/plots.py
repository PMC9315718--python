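"""Genome-wide statistic plots: raw scatter and smoothed line panels."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # file output only; no display required

import matplotlib.pyplot as plt
import pandas as pd

#: threshold line colours: red for quantile thresholds, blue for p-value ones
THRESHOLD_STYLES = {"quantile": "red", "pvalue": "blue"}


def plot_bsa(
    track: pd.DataFrame,
    kind: str = "scatter_raw",
    chromlist: Sequence[str] | None = None,
    threshold_lines: Sequence[tuple[float, str]] = (),
    output_path=None,
    fmt: str = "pdf",
):
    """Plot a statistic track, one panel per chromosome.

    ``kind`` is ``"scatter_raw"`` (per-SNP values) or ``"line_smoothed"``
    (tricube-smoothed values; requires a SMOOTHED column, as do threshold
    lines).  ``chromlist`` restricts and orders the panels; x is position
    in Mb.  ``threshold_lines`` draws horizontal lines at ``(value,
    style)`` with style ``"quantile"`` (red) or ``"pvalue"`` (blue).
    Returns the matplotlib figure; writes ``output_path`` when given
    (PDF by default).  The track itself is never modified.
    """
    if kind not in ("scatter_raw", "line_smoothed"):
        raise ValueError(f"unknown plot kind {kind!r}")
    column = "RAW" if kind == "scatter_raw" else "SMOOTHED"
    if column not in track.columns:
        raise ValueError(f"track has no {column} column required for kind={kind!r}")
    if threshold_lines and "SMOOTHED" not in track.columns:
        raise ValueError("threshold lines require a smoothed track")
    for _, style in threshold_lines:
        if style not in THRESHOLD_STYLES:
            raise ValueError(f"unknown threshold style {style!r}")

    all_chroms = list(pd.unique(track["CHROM"]))
    if chromlist:
        unknown = [c for c in chromlist if c not in all_chroms]
        if unknown:
            raise ValueError(f"unknown chromosomes {unknown}; valid names: {all_chroms}")
        chroms = list(chromlist)
    else:
        chroms = sorted(all_chroms)

    fig, axes = plt.subplots(
        1,
        len(chroms),
        figsize=(max(3.0 * len(chroms), 5.0), 3.2),
        sharey=True,
        squeeze=False,
    )
    stat_name = track["STAT"].iloc[0] if "STAT" in track.columns and len(track) else "statistic"
    for ax, chrom in zip(axes[0], chroms):
        sub = track[track["CHROM"] == chrom]
        x = sub["POS"].to_numpy() / 1e6
        if kind == "scatter_raw":
            ax.scatter(x, sub["RAW"], s=3, color="grey", rasterized=True)
        else:
            ax.plot(x, sub["SMOOTHED"], color="black", lw=1.2)
        for value, style in threshold_lines:
            ax.axhline(value, color=THRESHOLD_STYLES[style], lw=1.0)
        ax.set_title(str(chrom))
        ax.set_xlabel("position (Mb)")
    axes[0][0].set_ylabel(str(stat_name))
    fig.tight_layout()
    if output_path is not None:
        fig.savefig(output_path, format=fmt)
    return fig
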