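"""QUEST Bayesian adaptive staircase on log test/standard ratio.

The staircase maintains a discretised posterior over the threshold — here the
log10 ratio of test to standard numerosity at which the observer says "test
more" half the time.  Each trial's intensity is placed at the posterior mean
(the QUEST+ convention; mode and quantile placement are available), the
response updates the posterior through an assumed psychometric kernel, and
the caller converts the recommended log ratio to an integer test numerosity.

The assumed kernel is a cumulative Gaussian with guess rate ``gamma`` (0 for
a comparative 2IFC judgment, where "test more" at the threshold is 50% by
definition, not a floor) and lapse rate ``delta``.  The kernel sd ``beta``
defaults to the value implied by a Weber fraction of 0.25
(log10(1.25)/Phi^-1(0.75) ~= 0.1436).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

#: Kernel sd in log10 units implied by an assumed Weber fraction of 0.25.
DEFAULT_BETA = float(math.log10(1.25) / norm.ppf(0.75))


@dataclass(frozen=True)
class QuestState:
    """Immutable staircase state: grid, log posterior, kernel, history."""

    grid: np.ndarray  # strictly increasing candidate thresholds (log10 ratio)
    log_posterior: np.ndarray
    beta: float
    gamma: float
    delta: float
    placement: str = "mean"  # "mean" | "mode" | "quantile"
    quantile: float = 0.5
    history: tuple = field(default_factory=tuple)  # ((intensity, response), ...)

    def posterior(self) -> np.ndarray:
        p = np.exp(self.log_posterior - self.log_posterior.max())
        return p / p.sum()


def quest_create(
    prior_mean: float = 0.0,
    prior_sd: float = 0.25,
    beta: float = DEFAULT_BETA,
    gamma: float = 0.0,
    delta: float = 0.01,
    grid_range: tuple[float, float] = (-0.7, 0.7),
    grid_step: float = 0.02,
    placement: str = "mean",
) -> QuestState:
    """Fresh staircase with a normalised Gaussian prior on the threshold grid."""
    if grid_step <= 0 or grid_range[1] <= grid_range[0]:
        raise ValueError("grid must be increasing with positive step")
    n = int(round((grid_range[1] - grid_range[0]) / grid_step)) + 1
    grid = grid_range[0] + grid_step * np.arange(n)
    log_prior = -0.5 * ((grid - prior_mean) / prior_sd) ** 2
    log_prior -= np.log(np.exp(log_prior - log_prior.max()).sum()) + log_prior.max()
    return QuestState(grid, log_prior, beta, gamma, delta, placement)


def _kernel_p(state: QuestState, intensity: float, thresholds: np.ndarray) -> np.ndarray:
    """P("test more" | threshold) under the assumed psychometric kernel."""
    base = ndtr((intensity - thresholds) / state.beta)  # fast Gaussian CDF ufunc
    return state.gamma + (1.0 - state.gamma - state.delta) * base


def quest_update(state: QuestState, intensity: float, response: bool) -> QuestState:
    """Bayes-update the posterior with one (intensity, response) observation."""
    lo, hi = state.grid[0], state.grid[-1]
    if not lo <= intensity <= hi:
        warnings.warn(
            f"intensity {intensity:.3f} outside grid [{lo:.2f}, {hi:.2f}]; clamped",
            stacklevel=2,
        )
        intensity = float(np.clip(intensity, lo, hi))
    p = _kernel_p(state, intensity, state.grid)
    p = np.clip(p, 1e-10, 1.0 - 1e-10)
    log_post = state.log_posterior + (np.log(p) if response else np.log1p(-p))
    log_post -= np.log(np.exp(log_post - log_post.max()).sum()) + log_post.max()
    return replace(
        state,
        log_posterior=log_post,
        history=state.history + ((intensity, bool(response)),),
    )


def quest_next(state: QuestState) -> float:
    """Recommended next intensity (log10 test/standard ratio)."""
    post = state.posterior()
    if state.placement == "mean":
        return float(np.dot(post, state.grid))
    if state.placement == "mode":
        return float(state.grid[np.argmax(post)])
    if state.placement == "quantile":
        cdf = np.cumsum(post)
        return float(state.grid[np.searchsorted(cdf, state.quantile)])
    raise ValueError(f"unknown placement rule {state.placement!r}")


def quest_mean(state: QuestState) -> float:
    """Posterior-mean threshold estimate."""
    return float(np.dot(state.posterior(), state.grid))


def intensity_to_n_test(intensity: float, n_standard: int) -> int:
    """Convert a log10 ratio to an integer test numerosity (>= 1, half-up)."""
    return max(1, math.floor(n_standard * 10.0**intensity + 0.5))
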