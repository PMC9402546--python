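"""Psychometric fitting: cumulative-Gaussian MLE, PSE, JND, Weber fraction, bias.

For each participant x condition x standard numerosity, the proportion of
"test more numerous" responses as a function of test numerosity is fitted
with a cumulative Gaussian by maximising the Bernoulli likelihood over the
unbinned trials.  Derived indices:

* PSE  — the 50% point (test numerosity judged more numerous half the time);
* JND  — distance between the 50% and 75% points, i.e. Phi^-1(0.75) * sigma;
* Wf   — JND / N, the dimensionless discrimination threshold;
* bias — (PSE / N - 1) * 100, negative when the standard is overweighted
  (a symmetric standard perceived as less numerous pulls the PSE below N).

`PsychometricGaussian` is a scikit-learn style estimator (fit on test levels
X and boolean responses y); `fit_psychometric` wraps it for trial tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .observer import Z75

TRIAL_COLUMNS = [
    "participant_id",
    "experiment",
    "condition",
    "n_standard",
    "n_test",
    "standard_first",
    "response_test_more",
    "session",
    "trial_index",
]

MIN_TRIALS = 20
MIN_LEVELS = 5


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted summary for one participant x condition x standard numerosity."""

    pse: float
    jnd: float
    sigma: float
    wf: float
    bias_percent: float
    n_trials: int
    converged: bool
    log_likelihood: float


class PsychometricGaussian(BaseEstimator):
    """Cumulative-Gaussian psychometric function fitted by binomial MLE.

    Parameters
    ----------
    n_standard : reference numerosity; sets the PSE search box
        [pse_bounds[0]*N, pse_bounds[1]*N] and normalises Wf and bias.
    lapse_rate : fixed symmetric lapse mixed into the response probability
        (0 by default; expose for robustness refits).
    pse_bounds, sigma_bounds : optimisation box, as multiples of N.

    Attributes (after ``fit``)
    ----------
    pse_, sigma_, jnd_, wf_, bias_percent_ : fitted quantities.
    converged_ : False when optimisation failed, responses were all identical
        or a parameter is pinned at its bound (degenerate step data).
    log_likelihood_ : maximised Bernoulli log likelihood.
    """

    def __init__(
        self,
        n_standard: float = 100.0,
        lapse_rate: float = 0.0,
        pse_bounds: tuple[float, float] = (0.25, 2.5),
        sigma_bounds: tuple[float, float] = (1e-3, 2.0),
    ):
        self.n_standard = n_standard
        self.lapse_rate = lapse_rate
        self.pse_bounds = pse_bounds
        self.sigma_bounds = sigma_bounds

    def _prob(self, x: np.ndarray, pse: float, sigma: float) -> np.ndarray:
        p = norm.cdf((x - pse) / sigma)
        if self.lapse_rate:
            p = self.lapse_rate / 2.0 + (1.0 - self.lapse_rate) * p
        return p

    def fit(self, X, y) -> "PsychometricGaussian":
        x = np.asarray(X, dtype=float).ravel()
        r = np.asarray(y, dtype=bool).ravel()
        if x.shape != r.shape:
            raise ValueError("X and y must have the same length")
        n = self.n_standard
        lo = (self.pse_bounds[0] * n, self.sigma_bounds[0] * n)
        hi = (self.pse_bounds[1] * n, self.sigma_bounds[1] * n)

        def nll(theta):
            p = np.clip(self._prob(x, *theta), 1e-9, 1.0 - 1e-9)
            return -np.sum(np.where(r, np.log(p), np.log1p(-p)))

        best = None
        for sigma0 in (0.1 * n, 0.25 * n, 0.5 * n):
            res = minimize(
                nll,
                x0=np.array([np.clip(np.median(x), *[lo[0], hi[0]]), sigma0]),
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
            )
            if best is None or res.fun < best.fun:
                best = res
        self.pse_, self.sigma_ = map(float, best.x)
        self.log_likelihood_ = -float(best.fun)
        self.jnd_ = Z75 * self.sigma_
        self.wf_ = self.jnd_ / n
        self.bias_percent_ = (self.pse_ / n - 1.0) * 100.0
        degenerate = (
            r.all()
            or (~r).all()
            or self.sigma_ <= lo[1] * 1.01
            or not np.isfinite(best.fun)
        )
        self.converged_ = bool(best.success and not degenerate)
        self.n_trials_ = len(x)
        return self

    def predict_proba_more(self, X) -> np.ndarray:
        """P("test more") at test numerosities X under the fitted curve."""
        return self._prob(np.asarray(X, dtype=float).ravel(), self.pse_, self.sigma_)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba_more(X) >= 0.5

    def result(self) -> PsychometricFit:
        return PsychometricFit(
            pse=self.pse_,
            jnd=self.jnd_,
            sigma=self.sigma_,
            wf=self.wf_,
            bias_percent=self.bias_percent_,
            n_trials=self.n_trials_,
            converged=self.converged_,
            log_likelihood=self.log_likelihood_,
        )


def fit_psychometric(trials: pd.DataFrame, lapse_rate: float = 0.0) -> PsychometricFit:
    """Fit one cell (single participant x condition x standard numerosity).

    Requires >= 20 trials spanning >= 5 distinct test levels; trials from both
    sessions are expected to be pooled by the caller.
    """
    n_std = trials["n_standard"].unique()
    if len(n_std) != 1:
        raise ValueError("trials must come from a single standard numerosity")
    if len(trials) < MIN_TRIALS:
        raise ValueError(f"need >= {MIN_TRIALS} trials, got {len(trials)}")
    if trials["n_test"].nunique() < MIN_LEVELS:
        raise ValueError(f"need >= {MIN_LEVELS} distinct test levels")
    est = PsychometricGaussian(n_standard=float(n_std[0]), lapse_rate=lapse_rate)
    est.fit(trials["n_test"].to_numpy(), trials["response_test_more"].to_numpy())
    return est.result()


def weber_fraction(jnd: float, n_standard: float) -> float:
    """Wf = JND / N."""
    return jnd / n_standard


def bias_index(pse: float, n_standard: float) -> float:
    """Bias = (PSE/N - 1) x 100; negative = the standard is underestimated."""
    return (pse / n_standard - 1.0) * 100.0


def fit_all_cells(trials: pd.DataFrame, lapse_rate: float = 0.0) -> pd.DataFrame:
    """Fit every participant x condition x standard cell of a trial table.

    Returns one row per cell with the PsychometricFit fields; non-converged
    fits are kept with ``converged=False`` so callers can exclude and count
    them.
    """
    rows = []
    keys = ["participant_id", "condition", "n_standard"]
    for (pid, cond, n_std), cell in trials.groupby(keys, sort=True):
        try:
            fit = fit_psychometric(cell, lapse_rate=lapse_rate)
        except ValueError:
            # too few trials/levels in this cell (e.g. a tightly converged
            # staircase at small N): keep the row, flagged unusable
            fit = PsychometricFit(
                pse=float("nan"), jnd=float("nan"), sigma=float("nan"),
                wf=float("nan"), bias_percent=float("nan"),
                n_trials=len(cell), converged=False, log_likelihood=float("nan"),
            )
        rows.append(
            {
                "participant_id": pid,
                "condition": cond,
                "n_standard": n_std,
                **fit.__dict__,
            }
        )
    return pd.DataFrame(rows)
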