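import math

import numpy as np
import pytest

from abcdp.distances import DistanceSpec, KernelSpec
from abcdp.engine import (
    IndicatorTrace,
    posterior_mean,
    run_abcdp,
    run_abcdp_from_distances,
    run_rejection_abc,
    stream_distances,
)
from abcdp.privacy import PrivacyBudget, mmd_sensitivity
from abcdp.simulators import mixture_stream, sample_mixture_data
from abcdp.theory import flip_probability

SPEC = DistanceSpec(kind="mmd", kernel=KernelSpec(bandwidth=1.0))

# sensitivity used when a test wants a specific Laplace scale b: choosing
# epsilon = (c+1) * DELTA / b makes the calibrated scale exactly b
DELTA = 0.05


def _budget(eps_total, c, N, resample=False):
    return PrivacyBudget(eps_total, c, mmd_sensitivity(N, 1.0), resample)


def budget_of(b, c=1, delta=DELTA, resample=False):
    from abcdp.privacy import budget_of_noise_scale

    return budget_of_noise_scale(b, c, delta, resample)


class TestRejectionBaseline:
    def test_threshold_above_sup_accepts_everything(self, small_mixture_problem, rng):
        # rho <= 2 always holds under a kernel bounded by 1
        p = small_mixture_problem
        tr = run_rejection_abc(p["observed"], mixture_stream(20, 50, rng), 2.0, p["spec"])
        assert tr.count == 20

    def test_negative_threshold_accepts_nothing(self, small_mixture_problem, rng):
        p = small_mixture_problem
        obs = p["observed"]
        tr = run_rejection_abc(obs, mixture_stream(20, 50, rng), -0.1, p["spec"])
        assert tr.count == 0 and tr.termination_step == 20

    def test_indicators_match_brute_force_filter(self, small_mixture_problem, rng):
        p = small_mixture_problem
        eps = float(np.median(p["rho"]))
        obs = p["observed"]
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        tr = run_rejection_abc(obs, mixture_stream(30, 100, rng1), eps, p["spec"])
        _, rho = stream_distances(obs, mixture_stream(30, 100, rng2), p["spec"])
        expected = [1 if r <= eps else 0 for r in rho]  # independent filter
        assert tr.indicators.tolist() == expected

    def test_empty_stream_rejected(self, small_mixture_problem):
        with pytest.raises(ValueError, match="empty"):
            run_rejection_abc(small_mixture_problem["observed"], [], 0.1, SPEC)


class TestPrivateRun:
    def test_zero_noise_reduces_to_rejection_rule(self, small_mixture_problem):
        p = small_mixture_problem
        eps = float(np.median(p["rho"]))
        for seed in range(5):
            budget = _budget(math.inf, c=3, N=100)
            tr = run_abcdp_from_distances(
                p["rho"], p["thetas"], eps, budget, np.random.default_rng(seed)
            )
            expected = (p["rho"][: tr.termination_step] <= eps).astype(int)
            np.testing.assert_array_equal(tr.indicators, expected)

    def test_early_stop_at_c_acceptances(self, small_mixture_problem):
        p = small_mixture_problem
        eps = float(np.quantile(p["rho"], 0.5))  # plenty of sub-threshold pairs
        budget = _budget(math.inf, c=5, N=100)
        tr = run_abcdp_from_distances(
            p["rho"], p["thetas"], eps, budget, np.random.default_rng(0)
        )
        assert tr.count == 5
        assert tr.termination_step < p["rho"].size
        assert tr.indicators[-1] == 1  # loop breaks on the c-th acceptance

    def test_count_never_exceeds_cap(self, small_mixture_problem):
        p = small_mixture_problem
        for seed in range(10):
            budget = _budget(1.0, c=4, N=100, resample=bool(seed % 2))
            tr = run_abcdp_from_distances(
                p["rho"], p["thetas"], 0.3, budget, np.random.default_rng(seed)
            )
            assert tr.count <= 4

    def test_shortfall_is_a_valid_run(self, small_mixture_problem):
        p = small_mixture_problem
        budget = _budget(math.inf, c=10_000, N=100)
        tr = run_abcdp_from_distances(
            p["rho"], p["thetas"], float(np.median(p["rho"])), budget,
            np.random.default_rng(0),
        )
        assert tr.count < budget.c
        assert tr.termination_step == p["rho"].size

    def test_stream_and_distance_paths_agree(self, small_mixture_problem):
        # same noise stream + same distances => identical decisions
        p = small_mixture_problem
        obs = p["observed"]
        budget = _budget(2.0, c=3, N=100)
        tr_stream = run_abcdp(
            obs, mixture_stream(50, 100, np.random.default_rng(9)), 0.25, budget,
            p["spec"], np.random.default_rng(11),
        )
        thetas, rho = stream_distances(
            obs, mixture_stream(50, 100, np.random.default_rng(9)), p["spec"]
        )
        tr_dist = run_abcdp_from_distances(
            rho, thetas, 0.25, budget, np.random.default_rng(11)
        )
        np.testing.assert_array_equal(tr_stream.indicators, tr_dist.indicators)
        np.testing.assert_allclose(tr_stream.noisy_distances, tr_dist.noisy_distances)

    def test_lazy_stream_not_fully_consumed_on_early_stop(self, small_mixture_problem):
        p = small_mixture_problem
        consumed = []

        def counting_stream():
            rng = np.random.default_rng(21)
            for pair in mixture_stream(200, 50, rng):
                consumed.append(pair.index)
                yield pair

        budget = _budget(math.inf, c=2, N=100)
        tr = run_abcdp(p["observed"], counting_stream(), 0.5, budget, p["spec"],
                       np.random.default_rng(0))
        assert tr.count == 2
        assert len(consumed) == tr.termination_step < 200

    def test_single_step_flip_rate_matches_closed_form(self):
        # one fixed distance near the threshold; the engine's observed flip
        # frequency over seeded replicates must match G_b(|rho - eps|)
        rho, eps, b = 0.7, 0.2, 0.1
        budget = PrivacyBudget(
            epsilon_total=budget_of(b), c=1, delta_rho=DELTA, resample=False
        )
        n_rep = 20_000
        rng = np.random.default_rng(2024)
        base = rho <= eps
        flips = 0
        for _ in range(n_rep):
            tr = run_abcdp_from_distances([rho], [[0.0]], eps, budget, rng)
            flips += int(bool(tr.indicators[0]) != base)
        p_hat = flips / n_rep
        p_true = flip_probability(rho, eps, b)
        se = math.sqrt(p_true * (1 - p_true) / n_rep)
        assert abs(p_hat - p_true) <= 3 * se


class TestPosteriorMean:
    def test_single_accepted_sample_is_returned_exactly(self):
        thetas = np.array([[0.1, 0.9], [0.4, 0.6], [0.8, 0.2]])
        tr = IndicatorTrace(np.array([0, 1, 0]), np.zeros(3), None, thetas, False, 3)
        np.testing.assert_array_equal(posterior_mean(tr), thetas[1])

    def test_all_accepted_gives_arithmetic_mean(self, rng):
        thetas = rng.normal(size=(6, 3))
        tr = IndicatorTrace(np.ones(6, dtype=int), np.zeros(6), None, thetas, False, 6)
        np.testing.assert_allclose(posterior_mean(tr), thetas.mean(axis=0))

    def test_custom_integrand(self, rng):
        thetas = rng.normal(size=(4, 2))
        tr = IndicatorTrace(np.array([1, 0, 1, 1]), np.zeros(4), None, thetas, False, 4)
        expected = np.mean([np.sum(thetas[i] ** 2) for i in (0, 2, 3)])
        assert posterior_mean(tr, f=lambda th: np.sum(th**2)) == pytest.approx(expected)

    def test_no_accepted_samples_is_an_error(self):
        tr = IndicatorTrace(np.zeros(3, dtype=int), np.zeros(3), None, np.zeros((3, 2)), False, 3)
        with pytest.raises(ValueError, match="no accepted"):
            posterior_mean(tr)


class TestTraceInvariants:
    def test_count_and_indices_consistent(self, small_mixture_problem):
        p = small_mixture_problem
        budget = _budget(1.0, c=5, N=100)
        tr = run_abcdp_from_distances(
            p["rho"], p["thetas"], 0.3, budget, np.random.default_rng(3)
        )
        assert tr.count == int(tr.indicators.sum())
        np.testing.assert_array_equal(tr.indicators[tr.accepted_indices], 1)
        assert tr.accepted_thetas.shape == (tr.count, p["thetas"].shape[1])
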