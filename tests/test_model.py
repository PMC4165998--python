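"""Likelihood core: rate construction, closed-form MLE, genotyping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln
from scipy.stats import poisson

from svaf.model import (
    ABS_RATE_FLOOR,
    NOISE_FLOOR_EPS,
    ChannelRate,
    GenotypePrior,
    expected_rates,
    genotype_and_score,
    log_likelihood,
    mle_vaf,
)
from svaf.types import BinCount, GCRateTable, LibraryParams, ObservedCounts, SVCall

GRID = np.linspace(0.0, 1.0, 10_001)


def oracle_grid_loglik(rates, counts, eps=NOISE_FLOOR_EPS):
    """Independent brute-force log-likelihood on the p grid: per-channel
    Poisson log-pmf terms summed directly."""
    alpha = np.array([r.alpha for r in rates])
    beta = np.array([r.beta for r in rates])
    k = np.asarray(counts, dtype=float)
    floor = np.maximum(eps * np.maximum(alpha, alpha + beta), ABS_RATE_FLOOR)
    lam = np.maximum(alpha + np.outer(GRID, beta), floor)
    return (k * np.log(lam) - lam - gammaln(k + 1.0)).sum(axis=1)


def random_case(rng):
    """A random SV-shaped channel set with Poisson counts at a random p."""
    kind = rng.choice(["DEL", "DUP", "BAL"])
    rates = []
    if kind in ("DEL", "DUP"):
        sign = -1.0 if kind == "DEL" else 1.0
        for a in rng.uniform(0.5, 30.0, size=rng.integers(1, 20)):
            rates.append(ChannelRate(a, sign * a))
    n_junc = 2 if kind == "BAL" else 1
    for _ in range(n_junc):
        rates.append(ChannelRate(0.0, rng.uniform(0.5, 40.0)))
        rates.append(ChannelRate(0.0, rng.uniform(0.5, 40.0)))
    p_true = rng.uniform(0.0, 1.0)
    lam = np.array([r.rate(p_true) for r in rates])
    counts = rng.poisson(lam)
    return rates, counts.astype(float)


class TestMLE:
    def test_matches_grid_search_oracle(self):
        """Closed-form stationary-point MLE agrees with an exhaustive
        1e-4-step grid search over the same likelihood."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            rates, counts = random_case(rng)
            p_hat = mle_vaf(counts, rates)
            p_grid = GRID[int(np.argmax(oracle_grid_loglik(rates, counts)))]
            assert abs(p_hat - p_grid) <= 1e-3

    @pytest.mark.parametrize("kind", ["DEL", "DUP", "BAL"])
    @pytest.mark.parametrize("p", [0.0, 0.1, 0.3, 0.5, 0.9, 1.0])
    def test_noise_free_counts_recover_p_exactly(self, kind, p):
        """When counts equal their expectations, the MLE sits at truth."""
        rates = []
        if kind in ("DEL", "DUP"):
            sign = -1.0 if kind == "DEL" else 1.0
            rates += [ChannelRate(a, sign * a) for a in (5.0, 12.0, 2.5)]
        rates += [ChannelRate(0.0, 30.0), ChannelRate(0.0, 15.0)]
        counts = [r.rate(p) for r in rates]
        assert mle_vaf(counts, rates) == pytest.approx(p, abs=1e-9)

    def test_balanced_zero_evidence_gives_zero(self):
        rates = [ChannelRate(0.0, 25.0), ChannelRate(0.0, 10.0)]
        assert mle_vaf([0, 0], rates) == 0.0

    def test_unidentifiable_raises(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            mle_vaf([3.0], [ChannelRate(0.0, 0.0)])

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError, match="negative"):
            mle_vaf([-1.0], [ChannelRate(0.0, 5.0)])

    def test_rmse_halves_when_evidence_quadruples(self):
        """Identifiability: quadrupling expected counts halves the RMSE."""
        rng = np.random.default_rng(7)
        p = 0.3

        def rmse(scale, n=3000):
            rates = [ChannelRate(0.0, 30.0 * scale), ChannelRate(0.0, 16.0 * scale)]
            beta = np.array([r.beta for r in rates])
            draws = rng.poisson(beta * p, size=(n, 2)).astype(float)
            err = [mle_vaf(d, rates) - p for d in draws]
            return float(np.sqrt(np.mean(np.square(err))))

        ratio = rmse(4.0) / rmse(1.0)
        assert ratio == pytest.approx(0.5, rel=0.20)


class TestLogLikelihood:
    def test_equals_sum_of_poisson_logpmf(self):
        """Brute-force per-channel oracle with integer counts."""
        rng = np.random.default_rng(3)
        rates, counts = random_case(rng)
        for p in (0.05, 0.3, 0.77):
            lam = np.array(
                [
                    max(r.rate(p), max(NOISE_FLOOR_EPS * r.max_rate, ABS_RATE_FLOOR))
                    for r in rates
                ]
            )
            expected = poisson.logpmf(counts.astype(int), lam).sum()
            assert log_likelihood(counts, rates, p) == pytest.approx(expected, rel=1e-12)

    def test_grid_argmax_at_planted_rate(self):
        """Counts set exactly to rates(0.3) put the grid argmax at 0.3."""
        rates = [ChannelRate(a, -a) for a in (8.0, 8.0)] + [
            ChannelRate(0.0, 20.0),
            ChannelRate(0.0, 10.0),
        ]
        counts = [r.rate(0.3) for r in rates]
        ll = log_likelihood(counts, rates, GRID)
        assert GRID[int(np.argmax(ll))] == pytest.approx(0.3, abs=1e-4)

    def test_monotone_decreasing_for_zero_counts_balanced(self):
        rates = [ChannelRate(0.0, 25.0), ChannelRate(0.0, 10.0)]
        ll = log_likelihood([0, 0], rates, np.linspace(0.02, 1, 50))
        assert np.all(np.diff(ll) < 0)

    def test_multi_library_loglik_adds(self):
        rng = np.random.default_rng(11)
        lib1 = random_case(rng)
        lib2 = random_case(rng)
        merged = log_likelihood([(lib1[1], lib1[0]), (lib2[1], lib2[0])], None, 0.4)
        separate = log_likelihood(lib1[1], lib1[0], 0.4) + log_likelihood(
            lib2[1], lib2[0], 0.4
        )
        assert merged == pytest.approx(separate, rel=1e-12)

    def test_finite_at_boundaries(self):
        """The noise floor keeps p=0 and p=1 finite even with stray counts."""
        rates = [ChannelRate(5.0, -5.0), ChannelRate(0.0, 10.0)]
        for p in (0.0, 1.0):
            assert math.isfinite(log_likelihood([3, 2], rates, p))


class TestExpectedRates:
    def _shape(self, sv_type="DEL", thetas=(40, 50), junctions=1):
        bins = [] if sv_type in ("INV", "TRA") else [
            BinCount(gc_theta=th, width=100, n_i=0) for th in thetas
        ]
        return ObservedCounts(bins=bins, junctions=[(0, 0)] * junctions)

    def test_junction_rate_arithmetic(self):
        """c=0.025/bp, t=500, r=100, v_d=0.8 gives DRP rate 0.6 at p=0.1."""
        params = LibraryParams(
            read_length_r=100, insert_median_t=500, insert_spread=50,
            inserts_per_bp_c=0.025, offset_vd=0.8, offset_vs=0.7,
        )
        sv = SVCall("chr1", 1000, "chr1", 2000, "DEL")
        rates = expected_rates(sv, self._shape(), params, GCRateTable.flat(0.025))
        drp = rates[-2]
        assert drp.rate(0.1) == pytest.approx(0.6)
        sr = rates[-1]
        assert sr.rate(0.1) == pytest.approx(0.7 * 0.025 * 200 * 0.1)

    def test_del_bins_vanish_at_p1_and_match_gc_at_p0(self):
        params = LibraryParams(inserts_per_bp_c=0.02)
        table = GCRateTable.flat(0.02)
        sv = SVCall("chr1", 1000, "chr1", 1200, "DEL")
        rates = expected_rates(sv, self._shape(thetas=(30, 60)), params, table)
        for r in rates[:2]:
            assert r.rate(0.0) == pytest.approx(0.02 * 100)
            assert r.rate(1.0) == pytest.approx(0.0)

    def test_dup_bins_gain_one_copy(self):
        params = LibraryParams(inserts_per_bp_c=0.02)
        sv = SVCall("chr1", 1000, "chr1", 1200, "DUP")
        rates = expected_rates(
            sv, self._shape("DUP"), params, GCRateTable.flat(0.02)
        )
        assert rates[0].rate(1.0) == pytest.approx(2 * rates[0].rate(0.0))

    def test_nonpositive_span_drops_drp_channel(self):
        with pytest.warns(UserWarning, match="insert median"):
            params = LibraryParams(insert_median_t=150, read_length_r=100)
        sv = SVCall("chr1", 1000, "chr1", 3000, "INV")
        with pytest.warns(UserWarning, match="span coverage"):
            rates = expected_rates(
                sv, self._shape("INV", junctions=2), params, GCRateTable.flat(0.02)
            )
        assert rates[0].dropped and rates[2].dropped  # both junctions' DRP
        assert not rates[1].dropped  # soft-clip channel survives


class TestGenotyping:
    def test_posterior_matches_three_term_bayes_oracle(self):
        """Posterior over (AA, AB, BB) equals direct Bayes on the three
        Poisson likelihoods, for uniform and Hardy-Weinberg priors."""
        rates = [ChannelRate(6.0, -6.0), ChannelRate(0.0, 9.0), ChannelRate(0.0, 4.0)]
        counts = [4, 3, 1]
        for prior in (GenotypePrior(), GenotypePrior("hwe", 0.05)):
            est = genotype_and_score(counts, rates, prior)
            liks = np.exp([log_likelihood(counts, rates, pg) for pg in (0, 0.5, 1)])
            w = prior.weights()
            post = w * liks / np.sum(w * liks)
            assert est.error_prob == pytest.approx(post[0], rel=1e-9)
            assert np.exp(est.genotype_logliks) == pytest.approx(liks, rel=1e-9)
            assert ("AA", "AB", "BB")[int(np.argmax(post))] == est.genotype

    def test_posteriors_normalize(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            rates, counts = random_case(rng)
            est = genotype_and_score(counts, rates)
            w = GenotypePrior().weights()
            log_post = np.log(w) + np.array(est.genotype_logliks)
            post = np.exp(log_post - np.max(log_post))
            post /= post.sum()
            assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hwe_prior_weights(self):
        q = 0.01
        w = GenotypePrior("hwe", q).weights()
        assert w == pytest.approx([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        assert w.sum() == pytest.approx(1.0)

    def test_overwhelming_evidence_caps_score(self):
        rates = [ChannelRate(50.0, -50.0), ChannelRate(0.0, 40.0), ChannelRate(0.0, 20.0)]
        est = genotype_and_score([25, 22, 11], rates)  # textbook het pattern
        assert est.genotype == "AB"
        assert est.var_score == 99.0
        assert est.error_prob >= 1e-10

    def test_no_evidence_scores_reference(self):
        rates = [ChannelRate(50.0, -50.0), ChannelRate(0.0, 40.0), ChannelRate(0.0, 20.0)]
        est = genotype_and_score([50, 0, 0], rates)
        assert est.genotype == "AA"
        assert est.p_hat == 0.0
        assert est.var_score < 1.0

    def test_varscore_monotone_in_discordant_count(self):
        """With depth pinned at its heterozygous expectation, more junction
        evidence can only increase confidence."""
        rates = [ChannelRate(40.0, -40.0), ChannelRate(0.0, 30.0), ChannelRate(0.0, 15.0)]
        scores = [
            genotype_and_score([20, d, 0], rates).var_score for d in range(0, 16)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.data(),
    n_depth=st.integers(0, 6),
    n_junc=st.integers(1, 2),
)
def test_estimate_is_always_well_formed(data, n_depth, n_junc):
    """For arbitrary non-negative integer counts the estimate stays in
    [0, 1], the score is finite, and the genotype is one of the three."""
    rates = [
        ChannelRate(a, -a)
        for a in data.draw(
            st.lists(st.floats(0.5, 40.0), min_size=n_depth, max_size=n_depth)
        )
    ]
    for _ in range(n_junc):
        rates.append(ChannelRate(0.0, data.draw(st.floats(0.5, 50.0))))
    counts = [
        data.draw(st.integers(0, 200)) for _ in range(len(rates))
    ]
    est = genotype_and_score(counts, rates)
    assert 0.0 <= est.p_hat <= 1.0
    assert 0.0 <= est.error_prob <= 1.0
    assert 0.0 <= est.var_score <= 99.0
    assert est.genotype in ("AA", "AB", "BB")
    assert math.isfinite(est.loglik_at_p_hat)
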