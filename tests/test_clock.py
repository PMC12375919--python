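import itertools
import math

import numpy as np
import pytest

from pseudoclock.clock import (
    ClockObservation,
    ci_generations,
    closed_form_generations,
    count_likelihood,
    estimate_with_ci,
    indicator_likelihood,
    ml_generations,
    poisson_binomial_pmf,
    prob_pseudogenized,
    simulate_accumulation,
)

MU_LOF = 1.03e-9  # 0.103 x 1e-8


def poisson_binomial_brute_force(probs, d):
    """Oracle: enumerate all 2**T outcomes."""
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=len(probs)):
        if sum(outcome) != d:
            continue
        term = 1.0
        for x, p in zip(outcome, probs):
            term *= p if x else 1 - p
        total += term
    return total


class TestProbPseudogenized:
    def test_no_time_no_loss(self):
        assert prob_pseudogenized(1000, 0.0, MU_LOF) == 0.0

    def test_closed_form_value(self):
        p = prob_pseudogenized(1000, 6.30e5, MU_LOF)
        assert p == pytest.approx(1 - math.exp(-1.03e-9 * 1000 * 6.30e5), rel=1e-12)
        assert p == pytest.approx(0.477, abs=5e-4)

    def test_monotone_limit_to_one(self):
        ps = [prob_pseudogenized(1000, g, MU_LOF) for g in (1e5, 1e6, 1e7)]
        assert all(a < b for a, b in zip(ps, ps[1:]))
        assert prob_pseudogenized(1000, 1e12, MU_LOF) == pytest.approx(1.0)


class TestPoissonBinomial:
    @pytest.mark.parametrize("T", [1, 4, 8, 12])
    def test_matches_brute_force_enumeration(self, T):
        rng = np.random.default_rng(T)
        probs = rng.random(T)
        pmf = poisson_binomial_pmf(probs)
        for d in range(T + 1):
            assert pmf[d] == pytest.approx(
                poisson_binomial_brute_force(probs, d), rel=1e-10
            )
        assert pmf.sum() == pytest.approx(1.0)

    def test_equal_probabilities_reduce_to_binomial(self):
        from scipy.stats import binom

        pmf = poisson_binomial_pmf([0.3] * 10)
        assert pmf == pytest.approx(binom.pmf(range(11), 10, 0.3))


class TestCountLikelihood:
    def test_three_equal_genes_none_lost(self):
        # choose g so each gene is lost with probability exactly 1/2
        L = 1000.0
        g = math.log(2) / (MU_LOF * L)
        obs = ClockObservation(lengths=(L, L, L), n_pseudogenized=0)
        assert count_likelihood(obs, g, MU_LOF) == pytest.approx(0.125, rel=1e-9)

    def test_two_unequal_genes_hand_enumeration(self):
        # lengths chosen so p1 = 0.2 and p2 = 0.6
        g = 1.0
        L1 = -math.log(0.8) / MU_LOF
        L2 = -math.log(0.4) / MU_LOF
        obs = ClockObservation(lengths=(L1, L2), n_pseudogenized=1)
        assert count_likelihood(obs, g, MU_LOF) == pytest.approx(
            0.2 * 0.4 + 0.8 * 0.6, rel=1e-9
        )

    def test_all_lost_equals_product_of_probs(self):
        lengths = (800.0, 1000.0, 1500.0)
        g = 5e5
        obs = ClockObservation(lengths=lengths, n_pseudogenized=3)
        expected = math.prod(
            prob_pseudogenized(L, g, MU_LOF) for L in lengths
        )
        assert count_likelihood(obs, g, MU_LOF) == pytest.approx(expected, rel=1e-9)
        assert expected > 0

    def test_indicator_likelihood(self):
        g = 1.0
        L1 = -math.log(0.8) / MU_LOF
        L2 = -math.log(0.4) / MU_LOF
        obs = ClockObservation(
            lengths=(L1, L2), n_pseudogenized=1, indicators=(0, 1)
        )
        assert indicator_likelihood(obs, g, MU_LOF) == pytest.approx(
            0.8 * 0.6, rel=1e-9
        )


class TestMLGenerations:
    def test_matches_closed_form_for_equal_lengths(self):
        obs = ClockObservation(lengths=(1000.0,) * 88, n_pseudogenized=42)
        est = ml_generations(obs, MU_LOF)
        expected = closed_form_generations(42, 88, 1000.0, MU_LOF)
        assert expected == pytest.approx(6.30e5, rel=1e-3)
        assert est.g_hat == pytest.approx(expected, rel=1e-6)

    def test_none_lost_boundary(self):
        obs = ClockObservation(lengths=(1000.0,) * 10, n_pseudogenized=0)
        assert ml_generations(obs, MU_LOF).g_hat == 0.0

    def test_all_lost_open_upper_bound(self):
        obs = ClockObservation(lengths=(1000.0,) * 10, n_pseudogenized=10)
        with pytest.warns(UserWarning, match="open"):
            est = ml_generations(obs, MU_LOF)
        assert math.isinf(est.g_hat)

    def test_halving_mu_doubles_estimate(self):
        obs = ClockObservation(lengths=(1000.0,) * 88, n_pseudogenized=42)
        g_full = ml_generations(obs, 0.103 * 1e-8).g_hat
        g_half = ml_generations(obs, 0.103 * 0.5e-8).g_hat
        assert g_half == pytest.approx(2 * g_full, rel=1e-6)

    def test_monotone_in_number_lost(self):
        estimates = [
            ml_generations(
                ClockObservation(lengths=(1000.0,) * 20, n_pseudogenized=d),
                MU_LOF,
            ).g_hat
            for d in range(0, 20)
        ]
        assert all(a <= b for a, b in zip(estimates, estimates[1:]))

    def test_unequal_lengths_supported(self):
        rng = np.random.default_rng(3)
        lengths = tuple(rng.integers(500, 3000, 30).astype(float))
        obs = ClockObservation(lengths=lengths, n_pseudogenized=12)
        est = ml_generations(obs, MU_LOF)
        # the ML point should beat its neighbours on the likelihood
        for factor in (0.9, 1.1):
            assert count_likelihood(obs, est.g_hat, MU_LOF) >= count_likelihood(
                obs, est.g_hat * factor, MU_LOF
            )


class TestSimulateAccumulation:
    def test_zero_generations_all_zero(self):
        counts = simulate_accumulation([1000.0] * 10, 0.0, MU_LOF, 100, seed=1)
        assert (counts == 0).all()

    def test_mean_count_converges(self):
        g = 6.30e5
        counts = simulate_accumulation([1000.0] * 88, g, MU_LOF, 10_000, seed=2)
        p = prob_pseudogenized(1000.0, g, MU_LOF)
        se = math.sqrt(88 * p * (1 - p) / 10_000)
        assert counts.mean() == pytest.approx(88 * p, abs=3 * se)

    def test_unequal_lengths_mean(self):
        rng = np.random.default_rng(5)
        lengths = rng.integers(300, 3000, 40).astype(float)
        g = 4e5
        counts = simulate_accumulation(lengths, g, MU_LOF, 5000, seed=6)
        expected = sum(prob_pseudogenized(L, g, MU_LOF) for L in lengths)
        var = sum(
            prob_pseudogenized(L, g, MU_LOF)
            * (1 - prob_pseudogenized(L, g, MU_LOF))
            for L in lengths
        )
        assert counts.mean() == pytest.approx(
            expected, abs=3 * math.sqrt(var / 5000)
        )

    def test_fixed_seed_reproducible(self):
        a = simulate_accumulation([900.0] * 30, 3e5, MU_LOF, 50, seed=9)
        b = simulate_accumulation([900.0] * 30, 3e5, MU_LOF, 50, seed=9)
        assert (a == b).all()


class TestConfidenceIntervals:
    def test_none_lost_lower_bound_zero(self):
        obs = ClockObservation(lengths=(1000.0,) * 20, n_pseudogenized=0)
        lo, hi = ci_generations(obs, MU_LOF, method="exact")
        assert lo == 0.0
        assert hi > 0

    def test_interval_contains_ml_estimate(self):
        obs = ClockObservation(lengths=(1000.0,) * 88, n_pseudogenized=42)
        est = estimate_with_ci(obs, MU_LOF, seed=11, reps=500)
        assert est.ci_low <= est.g_hat <= est.ci_high

    def test_doubling_rate_halves_both_bounds(self):
        obs = ClockObservation(lengths=(1000.0,) * 40, n_pseudogenized=15)
        lo1, hi1 = ci_generations(obs, MU_LOF, method="exact")
        lo2, hi2 = ci_generations(obs, 2 * MU_LOF, method="exact")
        assert lo2 == pytest.approx(lo1 / 2, rel=1e-6)
        assert hi2 == pytest.approx(hi1 / 2, rel=1e-6)

    def test_all_lost_one_sided(self):
        obs = ClockObservation(lengths=(1000.0,) * 10, n_pseudogenized=10)
        lo, hi = ci_generations(obs, MU_LOF, method="exact")
        assert math.isinf(hi)
        assert lo > 0

    def test_simulation_and_exact_agree_roughly(self):
        obs = ClockObservation(lengths=(1000.0,) * 88, n_pseudogenized=42)
        lo_e, hi_e = ci_generations(obs, MU_LOF, method="exact")
        lo_s, hi_s = ci_generations(
            obs, MU_LOF, method="simulation", reps=4000, seed=13
        )
        assert lo_s == pytest.approx(lo_e, rel=0.15)
        assert hi_s == pytest.approx(hi_e, rel=0.15)
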