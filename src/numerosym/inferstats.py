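"""Inferential statistics: within-subject ANOVA, post-hocs, correlation BFs.

Covers the analysis toolkit used downstream of the psychometric fits:

* two-way repeated-measures ANOVA with per-effect Greenhouse-Geisser epsilon
  and both classical and partial eta squared;
* one-sample t-tests with Cohen's d (control-task accuracy vs chance);
* Bonferroni-adjusted paired post-hoc t-tests;
* Pearson correlation, plus the log10 default Bayes factor for a correlation
  computed from summary statistics (r, n) by numerical integration over a
  stretched-beta prior on rho;
* Jarque-Bera composite-normality test.

The RM-ANOVA sums of squares and epsilons are computed directly from the
cell matrix so the result carries SS-based effect sizes; standard routines
(scipy, pingouin) back the simpler tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats


# --------------------------------------------------------------------------
# Repeated-measures ANOVA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectResult:
    name: str
    F: float
    df_num: float
    df_den: float
    p: float
    gg_epsilon: float
    p_gg: float
    eta_squared: float
    partial_eta_squared: float


@dataclass(frozen=True)
class AnovaResult:
    effects: dict = field(default_factory=dict)  # name -> EffectResult

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.effects.values()])


def _helmert(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix with rows orthogonal to 1."""
    h = np.zeros((k - 1, k))
    for i in range(1, k):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -i
        h[i - 1] /= np.sqrt(i * (i + 1))
    return h


def _gg_epsilon(cells: np.ndarray, M: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for the effect with orthonormal contrast M.

    ``cells`` is subjects x (a*b) scores; epsilon = tr(E)^2 / (df tr(E^2))
    with E = M Sigma M' and Sigma the sample covariance of the cell scores.
    """
    df = M.shape[0]
    if df == 1:
        return 1.0
    sigma = np.cov(cells, rowvar=False, ddof=1)
    E = M @ sigma @ M.T
    tr = np.trace(E)
    tr2 = np.trace(E @ E)
    if tr2 <= 0:
        return 1.0
    return float(np.clip(tr**2 / (df * tr2), 1.0 / df, 1.0))


def rm_anova2(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant_id",
    within: tuple[str, str] = ("n_standard", "condition"),
) -> AnovaResult:
    """Two-way fully within-subject ANOVA on a complete balanced long table.

    F ratios use the subject-by-effect interaction error terms.  Each
    within-subject effect gets a Greenhouse-Geisser epsilon from its own
    contrast of the cell covariance matrix and a corrected p value.
    Eta squared is SS_effect / SS_total; partial eta squared is
    SS_effect / (SS_effect + SS_error).  Missing cells raise (no imputation).
    """
    fa, fb = within
    wide = data.pivot_table(
        index=subject, columns=[fa, fb], values=dv, aggfunc="mean", dropna=False
    )
    if wide.isna().any().any():
        raise ValueError("incomplete design: missing subject x cell combinations")
    a_levels = wide.columns.get_level_values(0).unique()
    b_levels = wide.columns.get_level_values(1).unique()
    s, a, b = len(wide), len(a_levels), len(b_levels)
    if s < 2:
        raise ValueError("need >= 2 subjects")
    # cells[s, i*b + j] ordered by (A level i, B level j)
    cells = wide.reindex(columns=pd.MultiIndex.from_product([a_levels, b_levels])).to_numpy()
    y = cells.reshape(s, a, b)

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_total = ((y - grand) ** 2).sum()
    ss_subj = a * b * ((m_s - grand) ** 2).sum()
    ss_a = s * b * ((m_a - grand) ** 2).sum()
    ss_b = s * a * ((m_b - grand) ** 2).sum()
    ss_ab = s * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    ha, hb = _helmert(a), _helmert(b)
    ua = np.ones((1, a)) / np.sqrt(a)
    ub = np.ones((1, b)) / np.sqrt(b)
    contrasts = {
        fa: np.kron(ha, ub),
        fb: np.kron(ua, hb),
        f"{fa}*{fb}": np.kron(ha, hb),
    }
    table = {
        fa: (ss_a, a - 1, ss_as, (s - 1) * (a - 1)),
        fb: (ss_b, b - 1, ss_bs, (s - 1) * (b - 1)),
        f"{fa}*{fb}": (ss_ab, (a - 1) * (b - 1), ss_abs, (s - 1) * (a - 1) * (b - 1)),
    }
    effects = {}
    for name, (ss_eff, df1, ss_err, df2) in table.items():
        ms_eff, ms_err = ss_eff / df1, ss_err / df2
        F = 0.0 if ms_err == 0 and ms_eff == 0 else ms_eff / ms_err
        p = float(stats.f.sf(F, df1, df2))
        eps = _gg_epsilon(cells, contrasts[name])
        p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps))
        denom = ss_eff + ss_err
        effects[name] = EffectResult(
            name=name,
            F=float(F),
            df_num=float(df1),
            df_den=float(df2),
            p=p,
            gg_epsilon=eps,
            p_gg=p_gg,
            eta_squared=float(ss_eff / ss_total) if ss_total > 0 else 0.0,
            partial_eta_squared=float(ss_eff / denom) if denom > 0 else 0.0,
        )
    return AnovaResult(effects)


# --------------------------------------------------------------------------
# t-tests and correlations
# --------------------------------------------------------------------------

def one_sample_t(x, mu: float = 0.0) -> tuple[float, float, float]:
    """One-sample t-test against ``mu``: (t, two-tailed p, Cohen's d)."""
    x = np.asarray(x, dtype=float)
    res = stats.ttest_1samp(x, mu)
    sd = x.std(ddof=1)
    d = 0.0 if sd == 0 else float((x.mean() - mu) / sd)
    return float(res.statistic), float(res.pvalue), d


def posthoc_bonferroni(pairs, m: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-tests with Bonferroni adjustment p_adj = min(1, m p).

    ``pairs`` is a list of (label, x, y); ``m`` defaults to len(pairs).
    """
    m = len(pairs) if m is None else m
    rows = []
    for label, x, y in pairs:
        diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
        t, p, d = one_sample_t(diff, 0.0)
        p_adj = min(1.0, m * p)
        rows.append(
            {
                "comparison": label,
                "t": t,
                "p": p,
                "p_adj": p_adj,
                "cohen_d": d,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson's r with two-tailed p."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def log10_bf_correlation(r: float, n: int, kappa: float = 1.0) -> float:
    """log10 default Bayes factor (H1 vs H0) for a Pearson correlation.

    Exact two-sided Bayes factor from the summary statistics (r, n) with a
    stretched symmetric beta(1/kappa, 1/kappa) prior on rho over (-1, 1);
    kappa = 1 (uniform prior) is the conventional default.  Positive values
    favour a nonzero correlation.

    The sampling density of r given rho enters through its rho-dependent part
    (1-rho^2)^((n-1)/2) (1-rho r)^{-(2n-3)/2} 2F1(1/2, 1/2; (2n-1)/2;
    (rho r + 1)/2); the constant in r cancels in the ratio to rho = 0.
    """
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be < 1 (degenerate correlation)")
    if n < 4:
        raise ValueError("need n >= 4")

    def rel_lik(rho: float) -> float:
        return (
            (1.0 - rho**2) ** ((n - 1) / 2.0)
            * (1.0 - rho * r) ** (-(2.0 * n - 3.0) / 2.0)
            * special.hyp2f1(0.5, 0.5, (2.0 * n - 1.0) / 2.0, (rho * r + 1.0) / 2.0)
        )

    a = 1.0 / kappa
    norm_const = special.beta(a, a) * 2.0 ** (2.0 * a - 1.0)

    def integrand(rho: float) -> float:
        prior = (1.0 - rho**2) ** (a - 1.0) / norm_const
        return rel_lik(rho) * prior

    num, err = integrate.quad(integrand, -1.0, 1.0, limit=200)
    bf10 = num / rel_lik(0.0)
    return float(np.log10(bf10))


def jarque_bera(x) -> tuple[float, float]:
    """Jarque-Bera composite normality test: (JB, asymptotic chi^2_2 p).

    JB = n/6 (skew^2 + (kurtosis - 3)^2 / 4).  Constant input raises; samples
    below n = 30 trigger a small-sample warning (the chi-square reference is
    asymptotic).
    """
    x = np.asarray(x, dtype=float)
    if x.std(ddof=0) == 0:
        raise ValueError("Jarque-Bera is undefined for a constant sample")
    if len(x) < 30:
        warnings.warn(
            f"Jarque-Bera chi-square reference is asymptotic; n={len(x)} < 30",
            stacklevel=2,
        )
    res = stats.jarque_bera(x)
    return float(res.statistic), float(res.pvalue)
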