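"""QUEST staircase: Bayes updates, placement, convergence."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from numerosym.observer import ObserverParams, p_test_more
from numerosym.staircase import (
    intensity_to_n_test,
    quest_create,
    quest_mean,
    quest_next,
    quest_update,
)


def test_fresh_state_recommends_prior_mean_and_normalizes():
    s = quest_create(prior_mean=0.0, prior_sd=0.2)
    assert quest_next(s) == pytest.approx(0.0, abs=1e-12)
    assert s.posterior().sum() == pytest.approx(1.0)
    assert np.all(np.diff(s.grid) > 0)
    # off-centre prior: grid truncation shifts the mean only marginally
    s2 = quest_create(prior_mean=0.1, prior_sd=0.2)
    assert quest_next(s2) == pytest.approx(0.1, abs=5e-3)


def test_flat_prior_posterior_proportional_to_likelihood():
    # near-flat prior on a 5-point grid: one update leaves posterior ~ likelihood
    s = quest_create(prior_mean=0.0, prior_sd=1e6, grid_range=(-0.2, 0.2), grid_step=0.1)
    s2 = quest_update(s, 0.0, True)
    lik = s.gamma + (1 - s.gamma - s.delta) * norm.cdf((0.0 - s.grid) / s.beta)
    np.testing.assert_allclose(s2.posterior(), lik / lik.sum(), rtol=1e-6)


def test_hand_computed_bayes_on_three_point_grid():
    # brute-force oracle: explicit prior x likelihood x likelihood on 3 cells
    s = quest_create(
        prior_mean=0.0, prior_sd=0.1, beta=0.1, gamma=0.0, delta=0.01,
        grid_range=(-0.1, 0.1), grid_step=0.1,
    )
    grid = np.array([-0.1, 0.0, 0.1])
    prior = np.exp(-0.5 * (grid / 0.1) ** 2)
    prior /= prior.sum()
    psi = lambda x, t: 0.99 * norm.cdf((x - t) / 0.1)
    post = prior * psi(0.05, grid) * (1 - psi(-0.05, grid))
    post /= post.sum()
    s = quest_update(s, 0.05, True)
    s = quest_update(s, -0.05, False)
    np.testing.assert_allclose(s.posterior(), post, rtol=1e-8)
    assert tuple(s.history) == ((0.05, True), (-0.05, False))


def test_opposite_responses_return_posterior_toward_prior():
    # with a lapse-free kernel the two likelihoods multiply to a symmetric
    # function of (threshold - intensity): the posterior mean returns exactly
    s0 = quest_create(delta=0.0)
    s = quest_update(quest_update(s0, 0.0, True), 0.0, False)
    assert quest_mean(s) == pytest.approx(quest_mean(s0), abs=1e-9)


def test_consistent_responses_shift_posterior_monotonically():
    # "test more" responses at the current estimate imply the 50% point lies
    # below the placement, so the threshold estimate must walk down; "test
    # less" responses walk it up
    s = quest_create()
    means = [quest_mean(s)]
    for _ in range(30):
        s = quest_update(s, quest_mean(s) + 0.05, True)
        means.append(quest_mean(s))
    assert np.all(np.diff(means) < 0)
    s = quest_create()
    ups = [quest_mean(s)]
    for _ in range(30):
        s = quest_update(s, quest_mean(s) - 0.05, False)
        ups.append(quest_mean(s))
    assert np.all(np.diff(ups) > 0)


def test_out_of_grid_intensity_clamped_with_warning():
    s = quest_create()
    with pytest.warns(UserWarning, match="clamped"):
        s2 = quest_update(s, 5.0, True)
    assert s2.history[-1][0] == pytest.approx(s.grid[-1])


def test_posterior_normalized_after_many_updates(rng):
    s = quest_create()
    for _ in range(200):
        s = quest_update(s, float(rng.uniform(-0.5, 0.5)), bool(rng.random() < 0.5))
        assert s.posterior().sum() == pytest.approx(1.0)
        assert np.all(np.isfinite(s.log_posterior))


def test_rounding_to_integer_test_numerosity():
    assert intensity_to_n_test(0.0, 100) == 100
    assert intensity_to_n_test(0.005, 100) == 101  # 101.16 -> 101
    assert intensity_to_n_test(-0.7, 1) == 1  # floor at 1
    assert intensity_to_n_test(math.log10(1.0051), 100) == 101  # just past .5 up


def _run_sim(true_threshold: float, n_trials: int, seed: int) -> float:
    params = ObserverParams(
        wf0=0.25, n_switch=100, alpha=0.5,
        bias_percent={("vertical", 100): (10**true_threshold - 1) * 100},
    )
    rng = np.random.default_rng(seed)
    s = quest_create()
    for _ in range(n_trials):
        x = quest_next(s)
        n_test = intensity_to_n_test(x, 100)
        p = p_test_more(n_test, 100, "vertical", params)
        s = quest_update(s, math.log10(n_test / 100), bool(rng.random() < p))
    return quest_mean(s)


def test_threshold_estimate_converges_to_generative_value():
    true_t = -0.03  # ~ -7% bias in log10 ratio units
    errs = [abs(_run_sim(true_t, 50, seed) - true_t) for seed in range(20)]
    assert np.median(errs) <= 2 * 0.02  # within 2 grid steps after 50 trials


def test_rmse_decreases_with_trial_count():
    true_t = -0.03
    rmse = {}
    for n_trials in (10, 50, 200):
        errs = [(_run_sim(true_t, n_trials, s) - true_t) ** 2 for s in range(200)]
        rmse[n_trials] = math.sqrt(np.mean(errs))
    assert rmse[200] < rmse[50] < rmse[10]
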