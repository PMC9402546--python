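"""Two-limb piecewise Weber-function fit on double-logarithmic coordinates.

The Weber fraction is constant (Wf0) up to a switching numerosity N', then
declines as a power law (N/N')^-alpha — flat-then-falling on log-log axes,
continuous at the breakpoint.  The fit minimises the residual sum of squares
in log10 Wf: for each candidate N' on a dense log-spaced grid, the
conditionally optimal (log10 Wf0, alpha) follow in closed form from linear
least squares with the continuity constraint built in; the profile over N'
picks the global minimum, ties broken toward the smaller N'.

`TwoLimbWeber` is a scikit-learn style estimator; `fit_two_limb` is the
functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class WeberCurveFit:
    """Fitted two-limb Weber curve."""

    wf0: float
    n_switch: float
    alpha: float
    rss: float  # residual sum of squares in log10 Wf
    n_points: int
    boundary: bool = False  # True when N' sits at the grid edge (flat data)


def default_switch_grid(lo: float = 8.0, hi: float = 400.0, num: int = 200) -> np.ndarray:
    return np.geomspace(lo, hi, num)


class TwoLimbWeber(BaseEstimator):
    """Breakpoint regression for the two-regime Weber curve.

    Parameters
    ----------
    switch_grid : candidate N' values (default 200 log-spaced over 8..400).
    nonneg_alpha : clamp the falling-limb exponent at 0 (the curve never
        rises with numerosity under the model).

    Attributes (after ``fit``)
    ----------
    wf0_, n_switch_, alpha_ : fitted plateau, breakpoint and exponent.
    rss_ : minimised residual sum of squares in log10 Wf.
    boundary_ : True when the breakpoint landed on the grid edge
        (all-flat data fit with alpha = 0).
    """

    def __init__(self, switch_grid: np.ndarray | None = None, nonneg_alpha: bool = True):
        self.switch_grid = switch_grid
        self.nonneg_alpha = nonneg_alpha

    @staticmethod
    def _profile_fit(lx: np.ndarray, ly: np.ndarray, ls: float, nonneg: bool):
        """Closed-form LS for (c = log10 Wf0, alpha) at breakpoint log10 N' = ls.

        Model: y = c - alpha * max(0, x - ls).  Normal equations in (c, alpha).
        """
        z = np.maximum(0.0, lx - ls)
        n = len(lx)
        sz, szz, sy, szy = z.sum(), (z * z).sum(), ly.sum(), (z * ly).sum()
        det = n * szz - sz * sz
        if det <= 1e-12:  # no point right of the breakpoint: alpha unidentified
            c, a = sy / n, 0.0
        else:
            c = (szz * sy - sz * szy) / det
            a = -(n * szy - sz * sy) / det
        if nonneg and a < 0:
            c, a = sy / n, 0.0
        resid = ly - (c - a * z)
        return c, a, float(resid @ resid)

    def fit(self, X, y) -> "TwoLimbWeber":
        n_values = np.asarray(X, dtype=float).ravel()
        wf_values = np.asarray(y, dtype=float).ravel()
        if n_values.shape != wf_values.shape:
            raise ValueError("X and y must have the same length")
        if len(n_values) < 4:
            raise ValueError("need >= 4 (N, Wf) points to fit three parameters")
        if np.any(wf_values <= 0):
            raise ValueError("Weber fractions must be positive")
        order = np.argsort(n_values)
        lx = np.log10(n_values[order])
        ly = np.log10(wf_values[order])
        grid = (
            default_switch_grid()
            if self.switch_grid is None
            else np.asarray(self.switch_grid, dtype=float)
        )
        # each candidate needs >= 2 points on one side to identify both limbs
        usable = grid[(np.searchsorted(lx, np.log10(grid)) >= 2)]
        if len(usable) == 0:
            usable = grid

        best = None
        for ns in usable:  # ascending: strict '<' keeps ties at the smaller N'
            c, a, rss = self._profile_fit(lx, ly, np.log10(ns), self.nonneg_alpha)
            if best is None or rss < best[3] - 1e-14:
                best = (ns, c, a, rss)
        ns, c, a, rss = best
        if a == 0.0:  # flat data: no breakpoint evidence; flag at the upper edge
            ns = float(usable[-1])
            self.boundary_ = True
        else:
            self.boundary_ = False
        self.n_switch_ = float(ns)
        self.wf0_ = float(10.0**c)
        self.alpha_ = float(a)
        self.rss_ = float(rss)
        self.n_points_ = len(lx)
        return self

    def predict(self, X) -> np.ndarray:
        """Weber fraction predicted at numerosities X."""
        n = np.asarray(X, dtype=float)
        return np.where(
            n <= self.n_switch_,
            self.wf0_,
            self.wf0_ * (n / self.n_switch_) ** (-self.alpha_),
        )

    def result(self) -> WeberCurveFit:
        return WeberCurveFit(
            wf0=self.wf0_,
            n_switch=round(self.n_switch_),
            alpha=self.alpha_,
            rss=self.rss_,
            n_points=self.n_points_,
            boundary=self.boundary_,
        )


def fit_two_limb(
    n_values, wf_values, grid: np.ndarray | None = None
) -> WeberCurveFit:
    """Fit the two-limb Weber curve to (N, Wf) points; see `TwoLimbWeber`."""
    est = TwoLimbWeber(switch_grid=grid)
    est.fit(n_values, wf_values)
    return est.result()


def group_mean_wf(fits) -> "tuple[np.ndarray, np.ndarray]":
    """Group-average Weber fraction per standard numerosity from a fits table.

    Non-converged fits are excluded.  Returns (n_values, mean_wf).
    """
    ok = fits[fits["converged"]]
    g = ok.groupby("n_standard")["wf"].mean()
    return g.index.to_numpy(dtype=float), g.to_numpy()
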