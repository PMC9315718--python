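"""Per-SNP linkage statistics for two-bulk segregant data.

Four statistics quantify, SNP by SNP, how strongly the allele-depth
pattern in two phenotypically extreme bulks departs from independent
Mendelian sampling:

* ``delta_snp_index`` — difference of within-bulk alternative-allele read
  fractions (the SNP-index), signed as high − low;
* ``euclidean_distance`` — Euclidean distance between the two bulks'
  allele-frequency vectors, optionally raised to a power;
* ``g_statistic`` — the 2×2 log-likelihood-ratio (G) test of allele-count
  independence between bulks;
* ``empirical_bayes_posterior`` — posterior probability that the SNP is
  completely linked to the causal locus under a hierarchical model of
  bulk composition and read sampling.

All four are deterministic functions of the observed counts.  Functions
accept scalars or equal-length numpy arrays in the ``BulkCounts`` fields,
so whole tracks are computed vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .snptable import validate_snp_table

STAT_NAMES = ("delta_snp", "ed", "g", "bayes")

#: Canonical columns of a statistic track.
TRACK_COLUMNS = ["CHROM", "POS", "STAT", "RAW"]


class BulkCounts(NamedTuple):
    """Reference/alternative read counts at one SNP in one bulk.

    Fields may be integers or equal-length integer arrays.
    """

    ref: object
    alt: object


def _check_informative(*bulks: BulkCounts) -> None:
    for b in bulks:
        total = np.asarray(b.ref) + np.asarray(b.alt)
        if np.any(total < 1):
            raise ValueError(
                "statistic undefined at zero per-bulk read depth; "
                "filter with require_informative first"
            )


def snp_index(b: BulkCounts):
    """Fraction of reads carrying the alternative allele: alt/(ref+alt)."""
    _check_informative(b)
    ref = np.asarray(b.ref, dtype=float)
    alt = np.asarray(b.alt, dtype=float)
    return alt / (ref + alt)


def delta_snp_index(high: BulkCounts, low: BulkCounts):
    """ΔSNP-index = snp_index(high) − snp_index(low); lies in [−1, 1]."""
    return snp_index(high) - snp_index(low)


def euclidean_distance(high: BulkCounts, low: BulkCounts, power: float = 1):
    """Euclidean distance between bulk allele-frequency vectors, to a power.

    ED = sqrt((f_ref,hi − f_ref,lo)² + (f_alt,hi − f_alt,lo)²); for
    biallelic data this equals √2·|ΔSNP-index|.  ``power`` exposes the
    ED⁴/ED⁵ variants used in some pipelines; default 1 returns raw ED.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    f_alt_hi = snp_index(high)
    f_alt_lo = snp_index(low)
    ed = np.sqrt((f_alt_hi - f_alt_lo) ** 2 + ((1 - f_alt_hi) - (1 - f_alt_lo)) ** 2)
    return ed**power


def g_statistic(high: BulkCounts, low: BulkCounts):
    """G = 2 Σ n·ln(n/n̂) over the 2×2 bulk-by-allele count table.

    Expected counts n̂ come from row/column marginals under independence;
    empty cells contribute 0 (the 0·ln 0 = 0 convention).  Invariant to
    swapping bulks and to swapping ref/alt in both bulks at once; under
    the null of equal bulk allele frequencies G is asymptotically χ²₁.
    """
    _check_informative(high, low)
    obs = np.stack(
        [
            np.asarray(high.ref, dtype=float),
            np.asarray(high.alt, dtype=float),
            np.asarray(low.ref, dtype=float),
            np.asarray(low.alt, dtype=float),
        ]
    )  # rows: cells (ref_hi, alt_hi, ref_lo, alt_lo); columns: SNPs
    row_hi = obs[0] + obs[1]
    row_lo = obs[2] + obs[3]
    col_ref = obs[0] + obs[2]
    col_alt = obs[1] + obs[3]
    total = row_hi + row_lo
    expected = (
        np.stack([row_hi * col_ref, row_hi * col_alt, row_lo * col_ref, row_lo * col_alt])
        / total
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * terms.sum(axis=0)
    return g if g.ndim else float(g)


@dataclass(frozen=True)
class BayesConfig:
    """Study-design inputs of the empirical-Bayes linkage posterior.

    Attributes
    ----------
    n_high, n_low : individuals pooled in each bulk.
    genome_length : total reference length in bp.
    linkage_span : span (bp) treated as completely linked to the causal
        locus; the prior probability of complete linkage for a random SNP
        is ``linkage_span / genome_length``.  Default 1 Mb.
    design : composition of the low (contrasting) bulk in an F2 design in
        which the high bulk is selected homozygous at the causal locus:
        ``"unselected"`` — random F2 individuals, causal-allele chromosome
        frequency 1/2; ``"contrasted"`` — phenotypically wildtype
        individuals (dominant-class selection), frequency 1/3.
    """

    n_high: int
    n_low: int
    genome_length: float
    linkage_span: float = 1e6
    design: str = "unselected"

    def __post_init__(self) -> None:
        if self.n_high < 1 or self.n_low < 1:
            raise ValueError("bulk sizes must be >= 1")
        if not 0 < self.linkage_span < self.genome_length:
            raise ValueError("need 0 < linkage_span < genome_length")
        if self.design not in ("unselected", "contrasted"):
            raise ValueError(f"unknown design {self.design!r}")

    @property
    def prior_linked(self) -> float:
        return self.linkage_span / self.genome_length

    @property
    def contrast_freq(self) -> float:
        """Causal-allele chromosome frequency in the low bulk under linkage."""
        return 0.5 if self.design == "unselected" else 1.0 / 3.0


def _bulk_marginal_loglik(ref, alt, n_ind: int, freq: float | None):
    """log Σ_m P(m) · Binom(alt | depth, m/2n) for one bulk.

    ``freq`` is the chromosome frequency of the alt allele in the bulk's
    latent composition prior Binomial(2n, freq); ``freq=None`` fixes the
    composition at m = 2n (all alt) — pass alt/ref swapped for m = 0.
    """
    alt = np.atleast_1d(np.asarray(alt, dtype=float))
    depth = alt + np.atleast_1d(np.asarray(ref, dtype=float))
    two_n = 2 * n_ind
    if freq is None:
        return binom.logpmf(alt, depth, 1.0)
    m = np.arange(two_n + 1)
    log_prior = binom.logpmf(m, two_n, freq)  # (m,)
    log_read = binom.logpmf(alt[:, None], depth[:, None], m[None, :] / two_n)
    return logsumexp(log_prior[None, :] + log_read, axis=1)


def empirical_bayes_posterior(high: BulkCounts, low: BulkCounts, cfg: BayesConfig):
    """Posterior probability of complete linkage given the read counts.

    Model: a random SNP is completely linked to the causal locus with
    prior π = linkage_span/genome_length.  Unlinked (H0), each bulk's
    alt-chromosome count m_b ~ Binomial(2n_b, 1/2) independently.
    Completely linked (H1), the selected (high) bulk is fixed at m = 2n
    or m = 0 depending on which observed allele is the causal one — both
    orientations averaged with equal weight — while the contrasting bulk
    draws m ~ Binomial(2n, f) at its design frequency f (1/2 unselected,
    1/3 phenotypically contrasted; 1−f for the opposite orientation).
    Reads are binomial given the composition:
    alt_b | m_b ~ Binomial(ref_b + alt_b, m_b/(2n_b)).  All marginal
    likelihoods are accumulated in log space.
    """
    _check_informative_allow_zero(high, low)
    log_pi = np.log(cfg.prior_linked)
    log_1mpi = np.log1p(-cfg.prior_linked)
    f = cfg.contrast_freq

    log_l0 = _bulk_marginal_loglik(high.ref, high.alt, cfg.n_high, 0.5)
    log_l0 = log_l0 + _bulk_marginal_loglik(low.ref, low.alt, cfg.n_low, 0.5)
    # orientation 1: alt allele causal (high bulk all-alt chromosomes)
    log_l1_alt = _bulk_marginal_loglik(high.ref, high.alt, cfg.n_high, None)
    log_l1_alt = log_l1_alt + _bulk_marginal_loglik(low.ref, low.alt, cfg.n_low, f)
    # orientation 2: ref allele causal (high bulk all-ref chromosomes)
    log_l1_ref = _bulk_marginal_loglik(high.alt, high.ref, cfg.n_high, None)
    log_l1_ref = log_l1_ref + _bulk_marginal_loglik(low.ref, low.alt, cfg.n_low, 1 - f)
    log_l1 = np.logaddexp(log_l1_alt, log_l1_ref) - np.log(2.0)

    log_num = log_pi + log_l1
    log_den = np.logaddexp(log_num, log_1mpi + log_l0)
    post = np.exp(log_num - log_den)
    return post if np.asarray(high.ref).ndim else float(post[0])


def _check_informative_allow_zero(*bulks: BulkCounts) -> None:
    # the Bayes posterior is well defined at zero depth (it returns the
    # prior), so only negative counts are rejected here
    for b in bulks:
        if np.any(np.asarray(b.ref) < 0) or np.any(np.asarray(b.alt) < 0):
            raise ValueError("negative read counts")


def compute_statistic(
    table: pd.DataFrame,
    method: str,
    *,
    power: float = 1,
    bayes: BayesConfig | None = None,
) -> pd.DataFrame:
    """Compute one statistic over a whole SNP table, returning a track.

    The track is a DataFrame with columns CHROM, POS, STAT, RAW; smoothing
    and significance testing add SMOOTHED and PVALUE columns downstream.
    """
    if method not in STAT_NAMES:
        raise ValueError(f"unknown method {method!r}; choose from {STAT_NAMES}")
    validate_snp_table(table)
    high = BulkCounts(
        table["AD_REF.HIGH"].to_numpy(), table["AD_ALT.HIGH"].to_numpy()
    )
    low = BulkCounts(table["AD_REF.LOW"].to_numpy(), table["AD_ALT.LOW"].to_numpy())
    if method == "delta_snp":
        raw = delta_snp_index(high, low)
    elif method == "ed":
        raw = euclidean_distance(high, low, power=power)
    elif method == "g":
        raw = g_statistic(high, low)
    else:
        if bayes is None:
            raise ValueError("method 'bayes' requires a BayesConfig")
        raw = empirical_bayes_posterior(high, low, bayes)
    return pd.DataFrame(
        {
            "CHROM": table["CHROM"].to_numpy(),
            "POS": table["POS"].to_numpy(),
            "STAT": method,
            "RAW": np.asarray(raw, dtype=float),
        }
    )
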