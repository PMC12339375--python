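"""Tests for the multiplicity histogram and all ANI/coverage estimators.

Expected values marked as oracle-derived were computed with independent
routes: sympy high-precision arithmetic, direct Poisson tail summation, a
grid/numeric ZIP maximum-likelihood fit, and Monte-Carlo draws from the
generative model.
"""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.stats import poisson

from covani.inference import (
    AniEstimate,
    CoveragePolicy,
    MultiplicityHistogram,
    SampleErrorModel,
    TooFewKmersError,
    adjusted_ani,
    bootstrap_ci,
    build_histogram,
    effective_coverage,
    estimate_ani,
    estimate_error_term,
    estimate_lambda,
    naive_ani,
    robust_mean_alpha,
    true_coverage,
)
from covani.sketch import GenomeSketch, SampleSketch, SketchParams

POLICY = CoveragePolicy()


def make_genome(hashes, params=None, genome_id="g", length=1_000_000):
    params = params or SketchParams()
    return GenomeSketch(genome_id=genome_id, genome_length=length, params=params,
                        kmers=np.asarray(sorted(hashes), dtype=np.uint64))


def make_sample(counts, params=None, total_bases=10_000_000, mean_len=150.0):
    params = params or SketchParams()
    return SampleSketch(sample_id="s", params=params, counts=dict(counts),
                        total_bases=total_bases, mean_read_length=mean_len,
                        paired=False, dedup_applied=False)


def hist_from(n_sketch, counts):
    return MultiplicityHistogram(n_sketch_kmers=n_sketch, counts=dict(counts))


def zip_draws(rng, n, p, lam):
    """i.i.d. zero-inflated Poisson: Pois(lam) * Bern(p)."""
    return rng.poisson(lam, n) * (rng.random(n) < p)


# ---------------------------------------------------------------------------
# build_histogram
# ---------------------------------------------------------------------------

class TestBuildHistogram:
    def test_hand_tally(self):
        genome = make_genome([10, 20, 30, 40, 50])
        sample = make_sample({20: 1, 30: 1, 40: 2, 99: 7})
        hist = build_histogram(genome, sample)
        assert hist.counts == {1: 2, 2: 1}
        assert hist.n_contained == 3
        assert hist.n_sketch_kmers == 5
        assert hist.mode_a == 1
        assert hist.median_nonzero == 1

    def test_full_containment(self):
        genome = make_genome(range(100))
        sample = make_sample({h: 1 for h in range(100)})
        hist = build_histogram(genome, sample)
        assert hist.counts == {1: 100}
        assert hist.n_contained == 100

    def test_disjoint(self):
        genome = make_genome([1, 2, 3])
        sample = make_sample({10: 4})
        hist = build_histogram(genome, sample)
        assert hist.counts == {}
        assert hist.n_contained == 0

    def test_parameter_mismatch_names_field(self):
        genome = make_genome([1], params=SketchParams(c=100))
        sample = make_sample({1: 1}, params=SketchParams(c=200))
        with pytest.raises(ValueError, match="c="):
            build_histogram(genome, sample)

    def test_median_even_count_interpolates(self):
        hist = hist_from(10, {1: 2, 3: 2})
        assert hist.median_nonzero == 2.0

    def test_mode_tie_prefers_smallest(self):
        hist = hist_from(10, {1: 5, 2: 5, 3: 1})
        assert hist.mode_a == 1


# ---------------------------------------------------------------------------
# naive ANI
# ---------------------------------------------------------------------------

class TestNaiveAni:
    def test_identity(self):
        assert naive_ani(hist_from(100, {1: 100}), 31) == 1.0

    def test_zero(self):
        assert naive_ani(hist_from(100, {}), 31) == 0.0

    def test_root_inverts_power(self):
        # containment 0.96^31 ~ 0.28271 must invert back to 0.96
        n = 10**6
        contained = round(0.96**31 * n)
        value = naive_ani(hist_from(n, {1: contained}), 31)
        assert value == pytest.approx(0.96, abs=1e-6)

    def test_empty_sketch_is_an_error(self):
        with pytest.raises(ValueError):
            naive_ani(hist_from(0, {}), 31)


# ---------------------------------------------------------------------------
# lambda estimator
# ---------------------------------------------------------------------------

class TestEstimateLambda:
    def test_direct_arithmetic(self):
        assert estimate_lambda(hist_from(300, {1: 100, 2: 50}), POLICY) == 1.0

    def test_requires_three_in_both_classes(self):
        assert estimate_lambda(hist_from(300, {1: 100, 2: 2}), POLICY) is None
        assert estimate_lambda(hist_from(300, {1: 2, 2: 100, 3: 2}), POLICY) is None

    def test_empty_histogram(self):
        assert estimate_lambda(hist_from(300, {}), POLICY) is None

    def test_mode_above_one(self):
        # a = 2: lambda = (N_3/N_2)*3
        hist = hist_from(1000, {1: 10, 2: 60, 3: 40})
        assert estimate_lambda(hist, POLICY) == pytest.approx(2.0)

    def test_monte_carlo_consistency(self, rng):
        draws = zip_draws(rng, 10**5, 0.9, 1.5)
        hist = MultiplicityHistogram.from_multiplicities(draws.size, draws)
        lam = estimate_lambda(hist, POLICY)
        assert abs(lam - 1.5) / 1.5 < 0.02


# ---------------------------------------------------------------------------
# adjusted ANI
# ---------------------------------------------------------------------------

class TestAdjustedAni:
    def test_correction_cancels(self):
        hist = hist_from(1000, {1: 500})
        assert adjusted_ani(hist, math.log(2.0), 31) == 1.0

    def test_large_lambda_limit(self):
        hist = hist_from(1000, {1: 700})
        assert adjusted_ani(hist, 50.0, 31) == pytest.approx(
            naive_ani(hist, 31), abs=1e-9)

    def test_high_precision_oracle(self):
        # sympy evaluation of ((0.3 / (1 - e^-0.5)))^(1/31)
        hist = hist_from(1000, {1: 300})
        got = adjusted_ani(hist, 0.5, 31)
        frac = sympy.Rational(300, 1000) / (1 - sympy.exp(-sympy.Rational(1, 2)))
        expect = float(frac ** sympy.Rational(1, 31))
        assert 0 < expect < 1  # not clamped
        assert got == pytest.approx(expect, abs=1e-9)

    def test_clamped_at_one(self):
        hist = hist_from(1000, {1: 900})
        assert adjusted_ani(hist, 0.1, 31) == 1.0

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            adjusted_ani(hist_from(10, {1: 5}), 0.0, 31)

    @settings(max_examples=40, deadline=None)
    @given(contained=st.integers(1, 999),
           lam=st.floats(0.05, 10.0, allow_nan=False))
    def test_adjusted_at_least_naive_and_clamped(self, contained, lam):
        hist = hist_from(1000, {1: contained})
        adj = adjusted_ani(hist, lam, 31)
        assert naive_ani(hist, 31) <= adj <= 1.0

    def test_monotone_nonincreasing_in_lambda(self):
        hist = hist_from(1000, {1: 400})
        lams = np.linspace(0.05, 6.0, 40)
        values = [adjusted_ani(hist, l, 31) for l in lams]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_deterministic_given_seed(self):
        hist = hist_from(2000, {1: 600, 2: 150, 3: 30})
        a = bootstrap_ci(hist, 31, POLICY, seed=42)
        b = bootstrap_ci(hist, 31, POLICY, seed=42)
        c = bootstrap_ci(hist, 31, POLICY, seed=43)
        assert a == b
        assert a != c

    def test_empty_intersection_absent(self):
        assert bootstrap_ci(hist_from(2000, {}), 31, POLICY, seed=0) is None

    def test_width_shrinks_with_n(self):
        small = hist_from(500, {1: 200, 2: 100})
        large = hist_from(10_000, {1: 4000, 2: 2000})
        lo_s, hi_s = bootstrap_ci(small, 31, POLICY, seed=0)
        lo_l, hi_l = bootstrap_ci(large, 31, POLICY, seed=0)
        assert (hi_l - lo_l) < (hi_s - lo_s)

    def test_interval_brackets_point_estimate(self):
        hist = hist_from(5000, {1: 700, 2: 180, 3: 40})
        lam = estimate_lambda(hist, POLICY)
        point = adjusted_ani(hist, lam, 31)
        lo, hi = bootstrap_ci(hist, 31, POLICY, seed=5)
        assert lo <= point <= hi


# ---------------------------------------------------------------------------
# effective and true coverage, error term
# ---------------------------------------------------------------------------

class TestEffectiveCoverage:
    def test_median_branch(self):
        assert effective_coverage(hist_from(200, {20: 100}), None, POLICY) == 20.0

    def test_lambda_branch(self):
        hist = hist_from(1000, {1: 100, 2: 90, 3: 20})
        assert effective_coverage(hist, 1.8, POLICY) == 1.8

    def test_median_fallback_when_lambda_absent(self):
        hist = hist_from(1000, {2: 100})
        assert effective_coverage(hist, None, POLICY) == 2.0

    def test_robust_mean_matches_direct_summation(self):
        # Poisson(5)-shaped histogram plus a huge outlier class
        lam = 5.0
        counts = {a: int(round(10_000 * poisson.pmf(a, lam))) for a in range(1, 16)}
        counts[500] = 50  # mobile-element-like outlier
        hist = hist_from(20_000, counts)
        m = hist.median_nonzero
        # independent alpha: direct cumulative summation of the Poisson pmf
        alpha = 0
        while 1.0 - poisson.cdf(alpha, m) >= 1e-10:
            alpha += 1
        assert robust_mean_alpha(m, 1e-10) == alpha
        expect = (sum(a * n for a, n in counts.items() if a < alpha)
                  / sum(n for a, n in counts.items() if a < alpha))
        got = effective_coverage(hist, None, POLICY)
        assert got == pytest.approx(expect)
        assert got < 6.0  # outlier excluded

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            effective_coverage(hist_from(100, {}), None, POLICY)


class TestErrorTerm:
    def test_user_epsilon_zero(self):
        sample = make_sample({1: 5})
        assert estimate_error_term(sample, 0.0, 31).E == 1.0

    def test_user_epsilon_formula(self):
        sample = make_sample({1: 5})
        em = estimate_error_term(sample, 0.005, 31)
        assert em.E == pytest.approx(0.995**31)

    def test_auto_formula(self):
        # n_1 = 100 singletons, n_2 = 450 doubletons -> E = 1 - 100/900
        counts = {}
        counts.update({i: 1 for i in range(100)})
        counts.update({1000 + i: 2 for i in range(450)})
        em = estimate_error_term(make_sample(counts), None, 31)
        assert em.E == pytest.approx(1 - 100 / 900)
        assert em.source == "auto"

    def test_auto_degenerate_falls_back(self):
        em = estimate_error_term(make_sample({1: 1, 2: 1}), None, 31)
        assert em.E == 1.0

    def test_auto_recovers_simulated_error_rate(self):
        from covani.inference import build_histogram  # noqa: F401
        from covani.sim import random_genome, sample_reads
        from covani.sketch import sketch_reads

        genome = random_genome(200_000, seed=60)
        reads, _ = sample_reads(genome, 25.0, 150, epsilon=0.005, seed=61)
        ssk = sketch_reads(reads, SketchParams(), dedup=False)
        em = estimate_error_term(ssk, None, 31)
        expect = 0.995**31
        assert abs(em.E - expect) / expect < 0.10


class TestTrueCoverage:
    def test_error_free_inverse(self):
        assert true_coverage(8.0, 150, 31, 1.0) == pytest.approx(10.0)

    def test_long_read_limit(self):
        assert true_coverage(3.0, 1e7, 31, 1.0) == pytest.approx(3.0, rel=1e-5)

    def test_with_error_term_oracle(self):
        got = true_coverage(1.0, 100, 31, 0.99**31)
        expect = float((sympy.Rational(100, 70)) / sympy.Float(0.99, 30) ** 31)
        assert got == pytest.approx(expect, rel=1e-9)

    def test_read_length_must_exceed_k(self):
        with pytest.raises(ValueError):
            true_coverage(1.0, 31, 31, 1.0)


# ---------------------------------------------------------------------------
# estimate_ani orchestration
# ---------------------------------------------------------------------------

class TestEstimateAni:
    def test_saturated_coverage_no_adjustment(self):
        genome = make_genome(range(100))
        sample = make_sample({h: 5 for h in range(100)})
        est = estimate_ani(genome, sample, seed=0)
        assert est.naive_ani == est.adjusted_ani == 1.0
        assert not est.adjustment_applied
        assert est.effective_coverage == 5.0

    def test_small_genome_skipped(self):
        genome = make_genome(range(40))
        sample = make_sample({h: 1 for h in range(40)})
        with pytest.raises(TooFewKmersError):
            estimate_ani(genome, sample)

    def test_empty_intersection(self):
        genome = make_genome(range(100))
        sample = make_sample({10_000: 3})
        est = estimate_ani(genome, sample)
        assert est.naive_ani == est.adjusted_ani == 0.0
        assert est.effective_coverage is None

    def test_low_coverage_adjustment_helps(self):
        from covani.sim import random_genome, sample_reads
        from covani.sketch import sketch_genome, sketch_reads

        params = SketchParams()
        genome = random_genome(1_000_000, seed=70)
        gsk = sketch_genome(genome, params, genome_id="g")
        reads, _ = sample_reads(genome, 0.3 * 150 / 120, 150, seed=71)
        ssk = sketch_reads(reads, params, dedup=False)
        em = SampleErrorModel(E=1.0, source="user_epsilon")
        est = estimate_ani(gsk, ssk, error_model=em, seed=72)
        assert est.adjustment_applied
        assert est.adjusted_ani > est.naive_ani
        assert est.adjusted_ani > 0.99
        assert est.naive_ani < 0.97

    def test_true_coverage_populated(self):
        genome = make_genome(range(100))
        sample = make_sample({h: 5 for h in range(100)}, mean_len=150.0)
        em = SampleErrorModel(E=1.0, source="user_epsilon")
        est = estimate_ani(genome, sample, error_model=em)
        assert est.true_coverage == pytest.approx(5.0 * 150 / 120)


# ---------------------------------------------------------------------------
# ZIP parameter recovery against a maximum-likelihood oracle
# ---------------------------------------------------------------------------

def zip_mle(draws):
    """Numeric ML fit of (p, lambda) for zero-inflated Poisson draws."""
    vals, cnts = np.unique(draws, return_counts=True)

    def nll(x):
        p, lam = x
        if not (1e-6 < p <= 1.0) or lam <= 1e-6:
            return 1e12
        logpmf = poisson.logpmf(vals, lam) + np.log(p)
        if vals[0] == 0:
            p0 = (1 - p) + p * math.exp(-lam)
            logpmf[0] = math.log(p0)
        return -(cnts * logpmf).sum()

    best = None
    for p0 in (0.3, 0.7, 1.0):
        for l0 in (0.3, 1.0, 3.0):
            res = minimize(nll, [p0, l0], method="Nelder-Mead")
            if best is None or res.fun < best.fun:
                best = res
    return best.x  # (p, lambda)


class TestZipConsistency:
    @pytest.mark.parametrize("lam", [0.2, 1.0, 3.0])
    @pytest.mark.parametrize("tau", [0.96, 1.0])
    def test_recovery_at_large_n(self, lam, tau):
        # at N = 1e5 the estimator's own sd can exceed 2% for small lambda,
        # so consistency is asserted on the mean over 30 replicates
        rng = np.random.default_rng(int(lam * 100) + int(tau * 10))
        p = tau**31
        lam_hats, tau_hats = [], []
        for _ in range(30):
            draws = zip_draws(rng, 10**5, p, lam)
            hist = MultiplicityHistogram.from_multiplicities(draws.size, draws)
            lam_hat = estimate_lambda(hist, POLICY)
            lam_hats.append(lam_hat)
            tau_hats.append(adjusted_ani(hist, lam_hat, 31))
        assert abs(np.mean(lam_hats) - lam) / lam < 0.02
        assert abs(np.mean(tau_hats) - tau) / tau < 0.02

    def test_agrees_with_ml_oracle_small_instance(self):
        rng = np.random.default_rng(99)
        draws = zip_draws(rng, 3000, 0.96**31, 1.0)
        hist = MultiplicityHistogram.from_multiplicities(draws.size, draws)
        lam_hat = estimate_lambda(hist, POLICY)
        p_ml, lam_ml = zip_mle(draws)
        assert abs(lam_hat - lam_ml) / lam_ml < 0.15
        tau_hat = adjusted_ani(hist, lam_hat, 31)
        tau_ml = p_ml ** (1 / 31)
        assert abs(tau_hat - tau_ml) < 0.01
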