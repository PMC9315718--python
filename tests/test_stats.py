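"""The four per-SNP linkage statistics against closed forms and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

import bulkseq as bq
from bulkseq.stats import BulkCounts


class TestSnpIndex:
    @pytest.mark.parametrize(
        "counts, expected",
        [((5, 15), 0.75), ((7, 0), 0.0), ((0, 9), 1.0)],
    )
    def test_closed_forms(self, counts, expected):
        assert bq.snp_index(BulkCounts(*counts)) == pytest.approx(expected)

    def test_zero_depth_raises(self):
        with pytest.raises(ValueError, match="zero per-bulk"):
            bq.snp_index(BulkCounts(0, 0))


class TestDeltaSnpIndex:
    @pytest.mark.parametrize(
        "high, low, expected",
        [
            ((5, 15), (12, 4), 0.5),
            ((9, 3), (9, 3), 0.0),
            ((0, 20), (20, 0), 1.0),
        ],
    )
    def test_closed_forms(self, high, low, expected):
        assert bq.delta_snp_index(BulkCounts(*high), BulkCounts(*low)) == pytest.approx(expected)


class TestEuclideanDistance:
    @pytest.mark.parametrize(
        "high, low, expected",
        [
            ((5, 15), (12, 4), math.sqrt(0.5)),  # alt fractions 0.75 vs 0.25
            ((3, 3), (5, 5), 0.0),
            ((0, 20), (20, 0), math.sqrt(2.0)),
        ],
    )
    def test_closed_forms(self, high, low, expected):
        assert bq.euclidean_distance(BulkCounts(*high), BulkCounts(*low)) == pytest.approx(expected)

    def test_power_variant(self):
        ed = bq.euclidean_distance(BulkCounts(5, 15), BulkCounts(12, 4))
        ed4 = bq.euclidean_distance(BulkCounts(5, 15), BulkCounts(12, 4), power=4)
        assert ed4 == pytest.approx(ed**4)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 200)] * 4).filter(lambda t: t[0] + t[1] and t[2] + t[3]))
    def test_identity_with_delta_snp(self, counts):
        rh, ah, rl, al = counts
        high, low = BulkCounts(rh, ah), BulkCounts(rl, al)
        ed = bq.euclidean_distance(high, low)
        delta = bq.delta_snp_index(high, low)
        assert ed == pytest.approx(math.sqrt(2) * abs(delta), abs=1e-12)


def g_oracle(rh, ah, rl, al):
    """Independent direct evaluation of 2 sum n ln(n/expected)."""
    obs = [[rh, ah], [rl, al]]
    total = rh + ah + rl + al
    g = 0.0
    for i in range(2):
        for j in range(2):
            if obs[i][j] > 0:
                expected = sum(obs[i]) * (obs[0][j] + obs[1][j]) / total
                g += obs[i][j] * math.log(obs[i][j] / expected)
    return 2.0 * g


class TestGStatistic:
    def test_balanced_table_is_zero(self):
        assert bq.g_statistic(BulkCounts(10, 10), BulkCounts(10, 10)) == pytest.approx(0.0)

    def test_diagonal_table_closed_form(self):
        g = bq.g_statistic(BulkCounts(10, 0), BulkCounts(0, 10))
        assert g == pytest.approx(40 * math.log(2), rel=1e-12)

    def test_matches_oracle_on_example(self):
        g = bq.g_statistic(BulkCounts(15, 5), BulkCounts(4, 12))
        assert g == pytest.approx(g_oracle(15, 5, 4, 12), rel=1e-12)

    def test_invariant_to_bulk_swap_and_allele_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            rh, ah, rl, al = rng.integers(1, 60, size=4)
            high, low = BulkCounts(rh, ah), BulkCounts(rl, al)
            g = bq.g_statistic(high, low)
            assert bq.g_statistic(low, high) == pytest.approx(g, rel=1e-12)
            assert bq.g_statistic(BulkCounts(ah, rh), BulkCounts(al, rl)) == pytest.approx(
                g, rel=1e-12
            )

    def test_chi2_limit_under_null(self):
        """With near-fixed bulk compositions, E[G] approaches the chi2_1 mean of 1.

        Bulk compositions are Binomial(2n, 1/2) with n = 500 so the extra
        between-bulk frequency variance (design effect ~1 + depth/(4n) at
        depth 50) stays inside the 3-SE band of the mean.
        """
        rng = np.random.default_rng(12)
        n_ind, depth, n_tables = 500, 50, 2000
        f_hi = rng.binomial(2 * n_ind, 0.5, size=n_tables) / (2 * n_ind)
        f_lo = rng.binomial(2 * n_ind, 0.5, size=n_tables) / (2 * n_ind)
        alt_hi = rng.binomial(depth, f_hi)
        alt_lo = rng.binomial(depth, f_lo)
        g = bq.g_statistic(
            BulkCounts(depth - alt_hi, alt_hi), BulkCounts(depth - alt_lo, alt_lo)
        )
        se = g.std(ddof=1) / math.sqrt(n_tables)
        assert abs(g.mean() - 1.0) <= 3 * se


def bayes_oracle(high, low, cfg):
    """Exhaustive summation over all (m_high, m_low) composition pairs.

    Probability-space double sum, structurally independent of the
    log-space per-bulk factorisation used by the implementation.
    """
    pi, f = cfg.prior_linked, cfg.contrast_freq
    nh, nl = 2 * cfg.n_high, 2 * cfg.n_low
    dh, dl = high.ref + high.alt, low.ref + low.alt
    mh = np.arange(nh + 1)
    ml = np.arange(nl + 1)
    read_h = binom.pmf(high.alt, dh, mh / nh)
    read_l = binom.pmf(low.alt, dl, ml / nl)
    joint_reads = np.outer(read_h, read_l)
    prior0 = np.outer(binom.pmf(mh, nh, 0.5), binom.pmf(ml, nl, 0.5))
    l0 = float((prior0 * joint_reads).sum())
    prior1 = np.zeros((nh + 1, nl + 1))
    prior1[nh, :] += 0.5 * binom.pmf(ml, nl, f)  # alt allele causal
    prior1[0, :] += 0.5 * binom.pmf(ml, nl, 1 - f)  # ref allele causal
    l1 = float((prior1 * joint_reads).sum())
    return pi * l1 / (pi * l1 + (1 - pi) * l0)


class TestEmpiricalBayes:
    CFG = bq.BayesConfig(n_high=30, n_low=30, genome_length=1e9, linkage_span=1e6)

    def test_zero_reads_returns_prior(self):
        post = bq.empirical_bayes_posterior(BulkCounts(0, 0), BulkCounts(0, 0), self.CFG)
        assert post == pytest.approx(self.CFG.prior_linked, rel=1e-12)

    def test_matches_enumeration_oracle_on_strong_signal(self):
        high, low = BulkCounts(0, 200), BulkCounts(132, 68)
        post = bq.empirical_bayes_posterior(high, low, self.CFG)
        assert post == pytest.approx(bayes_oracle(high, low, self.CFG), rel=1e-10)

    def test_monotone_in_frequency_divergence(self):
        strong = bq.empirical_bayes_posterior(BulkCounts(0, 50), BulkCounts(25, 25), self.CFG)
        weak = bq.empirical_bayes_posterior(BulkCounts(10, 40), BulkCounts(25, 25), self.CFG)
        assert strong > weak

    @pytest.mark.parametrize("design, freq", [("unselected", 0.5), ("contrasted", 1 / 3)])
    def test_design_sets_contrast_frequency(self, design, freq):
        cfg = bq.BayesConfig(n_high=10, n_low=10, genome_length=1e8, design=design)
        assert cfg.contrast_freq == pytest.approx(freq)

    def test_oracle_agreement_random_cases(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            n_high, n_low = rng.integers(1, 41, size=2)  # 2n <= 80
            cfg = bq.BayesConfig(
                n_high=int(n_high),
                n_low=int(n_low),
                genome_length=1e9,
                linkage_span=float(rng.integers(1e5, 1e7)),
                design=rng.choice(["unselected", "contrasted"]),
            )
            rh, ah, rl, al = rng.integers(0, 120, size=4)
            if rh + ah == 0 or rl + al == 0:
                continue
            high, low = BulkCounts(int(rh), int(ah)), BulkCounts(int(rl), int(al))
            post = bq.empirical_bayes_posterior(high, low, cfg)
            assert 0.0 <= post <= 1.0
            assert post == pytest.approx(bayes_oracle(high, low, cfg), rel=1e-10)


class TestComputeStatistic:
    def test_track_layout_and_determinism(self, small_sim):
        table, _ = small_sim
        track = bq.compute_statistic(table, "g")
        assert list(track.columns) == ["CHROM", "POS", "STAT", "RAW"]
        assert (track["STAT"] == "g").all()
        assert np.isfinite(track["RAW"]).all()
        again = bq.compute_statistic(table, "g")
        assert track.equals(again)

    def test_bayes_requires_config(self, small_sim):
        with pytest.raises(ValueError, match="BayesConfig"):
            bq.compute_statistic(small_sim[0], "bayes")

    def test_unknown_method_rejected(self, small_sim):
        with pytest.raises(ValueError, match="unknown method"):
            bq.compute_statistic(small_sim[0], "lod")

    def test_vectorised_matches_scalar(self, small_sim):
        table, _ = small_sim
        track = bq.compute_statistic(table, "delta_snp")
        row = table.iloc[17]
        expected = bq.delta_snp_index(
            BulkCounts(row["AD_REF.HIGH"], row["AD_ALT.HIGH"]),
            BulkCounts(row["AD_REF.LOW"], row["AD_ALT.LOW"]),
        )
        assert track["RAW"].iloc[17] == pytest.approx(expected)
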