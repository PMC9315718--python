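"""Tricube kernel smoothing and significance thresholds for statistic tracks.

Per-SNP statistics are noisy because read depth varies from site to site;
a Nadaraya–Watson weighted mean with a tricube kernel over a physical-
distance window recovers the slowly varying linkage signal.  Significance
is assessed either by an empirical quantile of the smoothed values or by
a permutation test that shuffles raw values across SNP positions
genome-wide and re-smooths, destroying linkage while preserving both the
marginal value distribution and the SNP spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry for tricube smoothing.

    ``width`` is the FULL window in bp (e.g. 5 Mb); the kernel half-width
    is ``width/2`` centred on the focal SNP.  Windows holding fewer than
    ``min_snps`` SNPs yield NaN; the default of 1 always includes the
    focal SNP, so every value is finite.
    """

    width: float
    min_snps: int = 1

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


@dataclass(frozen=True)
class ThresholdSpec:
    """Significance criterion: empirical quantile or permutation p-value.

    Exactly one mode is active.  ``quantile`` is a fractile in (0, 1),
    e.g. 0.95/0.99/0.999; ``alpha`` a p-value cutoff, e.g. 0.05/0.01/0.001.
    """

    mode: str
    quantile: float | None = None
    alpha: float | None = None
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("quantile", "pvalue"):
            raise ValueError(f"mode must be 'quantile' or 'pvalue', got {self.mode!r}")
        if self.mode == "quantile":
            if self.quantile is None or not 0 < self.quantile < 1:
                raise ValueError("quantile mode needs quantile in (0, 1)")
            if self.alpha is not None:
                raise ValueError("quantile mode must not set alpha")
        else:
            if self.alpha is None or not 0 < self.alpha < 1:
                raise ValueError("pvalue mode needs alpha in (0, 1)")
            if self.quantile is not None:
                raise ValueError("pvalue mode must not set quantile")
        if self.n_perm < 100:
            raise ValueError("n_perm < 100 gives too coarse a null")


def tricube_weight_matrix(pos: np.ndarray, half_width: float) -> sparse.csr_matrix:
    """Row-normalised tricube weights between SNPs of one sorted chromosome.

    Entry (i, j) is w_ij/Σ_j w_ij with w = (1 − (d/h)³)³ for |pos_j −
    pos_i| = d ≤ h and 0 beyond.  The focal SNP contributes weight 1 to
    its own row.  The matrix depends only on positions, so permutation
    re-smoothing reuses it as a sparse mat-vec.
    """
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    lo = np.searchsorted(pos, pos - half_width, side="left")
    hi = np.searchsorted(pos, pos + half_width, side="right")
    counts = hi - lo
    rows = np.repeat(np.arange(n), counts)
    cols = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)]) if n else np.array([], int)
    d = np.abs(pos[cols] - pos[rows]) / half_width
    w = np.clip(1.0 - d**3, 0.0, None) ** 3
    mat = sparse.csr_matrix((w, (rows, cols)), shape=(n, n))
    norm = np.asarray(mat.sum(axis=1)).ravel()
    inv = sparse.diags(1.0 / norm)
    return inv @ mat


def _check_sorted(track: pd.DataFrame) -> None:
    for chrom, grp in track.groupby("CHROM", sort=False):
        if not grp["POS"].is_monotonic_increasing:
            raise ValueError(
                f"track not sorted by position on chromosome {chrom}; sort by (CHROM, POS) first"
            )


def tricube_smooth(track: pd.DataFrame, window: WindowSpec) -> pd.DataFrame:
    """Fill the SMOOTHED column of a track by tricube-weighted local means.

    Smoothing never crosses chromosome boundaries.  It is linear in the
    raw values, and each smoothed value is a convex combination of raw
    values, hence stays within the per-chromosome raw range.
    """
    _check_sorted(track)
    if not np.all(np.isfinite(track["RAW"].to_numpy(dtype=float))):
        raise ValueError("RAW contains non-finite values")
    track = track.reset_index(drop=True)
    out = track.copy()
    h = window.width / 2.0
    smoothed = np.empty(len(track))
    for _, grp in track.groupby("CHROM", sort=False):
        idx = grp.index.to_numpy()
        mat = tricube_weight_matrix(grp["POS"].to_numpy(), h)
        vals = mat @ grp["RAW"].to_numpy(dtype=float)
        if window.min_snps > 1:
            counts = np.diff(mat.indptr)
            vals = np.where(counts >= window.min_snps, vals, np.nan)
        smoothed[idx] = vals
    out["SMOOTHED"] = smoothed
    return out


def quantile_threshold(values, q: float) -> float:
    """Empirical quantile with linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a quantile of no values")
    if not 0 < q < 1:
        raise ValueError("quantile must be in (0, 1)")
    return float(np.quantile(values, q))


def permutation_pvalues(
    track: pd.DataFrame,
    window: WindowSpec,
    spec: ThresholdSpec,
    *,
    absolute: bool = False,
) -> pd.DataFrame:
    """Fill the PVALUE column by a genome-wide value-shuffling permutation test.

    Each permutation shuffles the raw values uniformly at random across
    all SNP positions genome-wide (positions fixed, values permuted) and
    re-smooths; the smoothed values of all permutations are pooled into
    one null sample.  ``pvalue_i = (1 + #{null >= smoothed_i}) /
    (1 + |null|)`` — the +1 keeps p > 0.  With ``absolute=True`` (for
    signed statistics such as ΔSNP) both observed and null smoothed
    values are compared in absolute value.  Deterministic given
    ``spec.seed``.
    """
    _check_sorted(track)
    track = track.reset_index(drop=True)
    rng = np.random.default_rng(spec.seed)
    h = window.width / 2.0

    groups = []  # (index, weight matrix) per chromosome, in track order
    for _, grp in track.groupby("CHROM", sort=False):
        groups.append((grp.index.to_numpy(), tricube_weight_matrix(grp["POS"].to_numpy(), h)))

    raw = track["RAW"].to_numpy(dtype=float)
    observed = np.empty(len(track))
    for idx, mat in groups:
        observed[idx] = mat @ raw[idx]

    null = np.empty(spec.n_perm * len(track))
    for p in range(spec.n_perm):
        perm = rng.permutation(raw)
        block = np.empty(len(track))
        for idx, mat in groups:
            block[idx] = mat @ perm[idx]
        null[p * len(track) : (p + 1) * len(track)] = block

    obs_cmp = np.abs(observed) if absolute else observed
    null_cmp = np.sort(np.abs(null) if absolute else null)
    # tie tolerance: weighted means of permuted values differ from the
    # observed ones by rounding even when the data are exchanged exactly,
    # so "null >= observed" is counted with a small relative slack
    slack = 1e-9 * (1.0 + np.abs(obs_cmp))
    n_ge = len(null_cmp) - np.searchsorted(null_cmp, obs_cmp - slack, side="left")
    out = track.copy()
    out["SMOOTHED"] = observed
    out["PVALUE"] = (1.0 + n_ge) / (1.0 + len(null_cmp))
    return out
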