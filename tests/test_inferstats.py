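"""Inferential layer: SS oracle for the RM-ANOVA, t/correlation/BF/JB checks."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from numerosym.inferstats import (
    jarque_bera,
    log10_bf_correlation,
    one_sample_t,
    pearson_correlation,
    posthoc_bonferroni,
    rm_anova2,
)

# ---------------------------------------------------------------------------
# fixed 4 subjects x 2 (A) x 3 (B) toy table for the hand-computed SS oracle
# ---------------------------------------------------------------------------
TOY = np.array(
    [  # subjects x A x B
        [[3.0, 4.0, 6.0], [5.0, 6.0, 9.0]],
        [[2.0, 4.0, 5.0], [4.0, 7.0, 8.0]],
        [[4.0, 5.0, 7.0], [6.0, 6.0, 10.0]],
        [[3.0, 3.0, 6.0], [5.0, 8.0, 9.0]],
    ]
)


def toy_frame():
    rows = []
    for s in range(4):
        for i in range(2):
            for j in range(3):
                rows.append(
                    {"participant_id": f"S{s}", "A": f"a{i}", "B": f"b{j}",
                     "value": TOY[s, i, j]}
                )
    return pd.DataFrame(rows)


def manual_ss_oracle(y):
    """Explicit-loop sums-of-squares decomposition (independent of the package)."""
    s, a, b = y.shape
    g = y.mean()
    m_s = y.mean(axis=(1, 2)); m_a = y.mean(axis=(0, 2)); m_b = y.mean(axis=(0, 1))
    ss_a = s * b * sum((m - g) ** 2 for m in m_a)
    ss_b = s * a * sum((m - g) ** 2 for m in m_b)
    ss_ab = 0.0
    for i in range(a):
        for j in range(b):
            ss_ab += s * (y[:, i, j].mean() - m_a[i] - m_b[j] + g) ** 2
    ss_as = 0.0
    for k in range(s):
        for i in range(a):
            ss_as += b * (y[k, i, :].mean() - m_s[k] - m_a[i] + g) ** 2
    ss_bs = 0.0
    for k in range(s):
        for j in range(b):
            ss_bs += a * (y[k, :, j].mean() - m_s[k] - m_b[j] + g) ** 2
    ss_total = ((y - g) ** 2).sum()
    ss_subj = a * b * sum((m - g) ** 2 for m in m_s)
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs
    F_a = (ss_a / (a - 1)) / (ss_as / ((s - 1) * (a - 1)))
    F_b = (ss_b / (b - 1)) / (ss_bs / ((s - 1) * (b - 1)))
    F_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((s - 1) * (a - 1) * (b - 1)))
    return {
        "F": {"A": F_a, "B": F_b, "A*B": F_ab},
        "df": {"A": (a - 1, (s - 1) * (a - 1)),
               "B": (b - 1, (s - 1) * (b - 1)),
               "A*B": ((a - 1) * (b - 1), (s - 1) * (a - 1) * (b - 1))},
        "eta2": {"A": ss_a / ss_total, "B": ss_b / ss_total, "A*B": ss_ab / ss_total},
    }


def test_rm_anova_matches_manual_ss_oracle():
    res = rm_anova2(toy_frame(), dv="value", within=("A", "B"))
    oracle = manual_ss_oracle(TOY)
    for eff in ("A", "B", "A*B"):
        e = res[eff]
        assert e.F == pytest.approx(oracle["F"][eff], abs=1e-8)
        assert (e.df_num, e.df_den) == oracle["df"][eff]
        assert e.p == pytest.approx(stats.f.sf(*(oracle["F"][eff], *oracle["df"][eff])))
        assert e.eta_squared == pytest.approx(oracle["eta2"][eff], abs=1e-10)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_rm_anova_matches_pingouin(seed):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(9):
        base = rng.normal()
        for i in range(4):
            for j in range(3):
                rows.append(
                    {"participant_id": f"S{s}", "A": f"a{i}", "B": f"b{j}",
                     "value": base + 0.4 * i - 0.2 * j + rng.normal(0, 0.6)}
                )
    df = pd.DataFrame(rows)
    mine = rm_anova2(df, dv="value", within=("A", "B"))
    with pytest.warns(UserWarning):  # pingouin flags its own two-way epsilons
        ref = pg.rm_anova(
            data=df, dv="value", within=["A", "B"], subject="participant_id",
            detailed=True,
        ).set_index("Source")
    for eff, src in (("A", "A"), ("B", "B"), ("A*B", "A * B")):
        assert mine[eff].F == pytest.approx(ref.loc[src, "F"], rel=1e-8)
        assert mine[eff].p == pytest.approx(ref.loc[src, "p_unc"], rel=1e-6)
    # main-effect epsilons: standard definition = GG epsilon of the
    # subject x factor table collapsed over the other factor
    for eff, other in (("A", "B"), ("B", "A")):
        pivot = df.pivot_table(index="participant_id", columns=eff, values="value")
        assert mine[eff].gg_epsilon == pytest.approx(
            pg.epsilon(pivot, correction="gg"), rel=1e-8
        )


def test_rm_anova_degenerate_and_structural_cases():
    df = toy_frame()
    # equal condition means within every subject -> F for that factor is 0
    flat = df.copy()
    flat["value"] = flat.groupby(["participant_id", "B"])["value"].transform("mean")
    res = rm_anova2(flat, dv="value", within=("A", "B"))
    assert res["A"].F == pytest.approx(0.0, abs=1e-20)
    # 2-level factor has trivially spherical covariance
    assert rm_anova2(df, dv="value", within=("A", "B"))["A"].gg_epsilon == 1.0
    with pytest.raises(ValueError, match="missing"):
        rm_anova2(df.iloc[:-1], dv="value", within=("A", "B"))


def test_gg_correction_is_conservative_for_clear_effects():
    # shrinking both dfs by epsilon raises p for F clearly above 1 (the
    # regime where sphericity correction matters); near F ~ 1 the two df
    # changes can cancel, so the check is restricted accordingly
    res = rm_anova2(toy_frame(), dv="value", within=("A", "B"))
    checked = 0
    for e in res.effects.values():
        if e.gg_epsilon < 1 and e.F > 2:
            assert e.p_gg >= e.p
            checked += 1
    assert checked >= 1


def test_one_sample_t_formula_oracle():
    x = np.array([0.2, 0.5, 0.1, 0.4, 0.35, 0.25])
    t, p, d = one_sample_t(x, 0.5)
    n = len(x)
    t_manual = (x.mean() - 0.5) / (x.std(ddof=1) / np.sqrt(n))
    assert t == pytest.approx(t_manual, rel=1e-12)
    assert p == pytest.approx(2 * stats.t.sf(abs(t_manual), n - 1), rel=1e-12)
    assert d == pytest.approx((x.mean() - 0.5) / x.std(ddof=1), rel=1e-12)
    # centred sample: t = 0, d = 0
    t0, _, d0 = one_sample_t(np.array([1.0, 3.0]), 2.0)
    assert t0 == 0.0 and d0 == 0.0


def test_bonferroni_adjustment_and_threshold():
    res = posthoc_bonferroni(
        [("a", np.arange(8.0), np.arange(8.0) - 1.0)], m=8, alpha=0.05
    )
    assert res.loc[0, "p_adj"] == pytest.approx(min(1, 8 * res.loc[0, "p"]))
    capped = posthoc_bonferroni(
        [("b", np.array([1.0, 2.0, 1.5, 2.1]), np.array([1.4, 1.9, 1.6, 2.0]))], m=8
    )
    assert capped.loc[0, "p_adj"] == 1.0
    # the design's corrected alpha: 0.05 / 8 comparisons
    assert 0.05 / 8 == pytest.approx(0.00625)


def test_pearson_r_and_p_match_printed_convention():
    # construct a sample with exactly r = 0.51 at n = 23, p should be ~0.014
    rng = np.random.default_rng(3)
    x = rng.standard_normal(23)
    x -= x.mean()
    e = rng.standard_normal(23)
    e -= e.mean()
    e -= e @ x / (x @ x) * x  # orthogonalize (stays centred)
    target = 0.51
    y = target * x / np.linalg.norm(x) + np.sqrt(1 - target**2) * e / np.linalg.norm(e)
    r, p = pearson_correlation(x, y)
    assert r == pytest.approx(0.51, abs=1e-12)
    # exact two-sided p at r = 0.51, n = 23 is 0.0129; a value reported as
    # 0.014 is consistent with an r that rounds to 0.51 (e.g. 0.505)
    t = 0.51 * np.sqrt(21) / np.sqrt(1 - 0.51**2)
    assert p == pytest.approx(2 * stats.t.sf(t, 21), rel=1e-9)
    assert 0.012 < p < 0.015
    assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
    assert pearson_correlation(x, e)[0] == pytest.approx(0.0, abs=1e-12)


def test_log10_bf_monotonicity_and_sign():
    assert log10_bf_correlation(0.0, 23) < 0  # no effect: evidence for H0
    bfs = [log10_bf_correlation(r, 23) for r in (0.1, 0.3, 0.5, 0.7)]
    assert np.all(np.diff(bfs) > 0)
    assert log10_bf_correlation(0.5, 60) > log10_bf_correlation(0.5, 23)
    with pytest.raises(ValueError):
        log10_bf_correlation(1.0, 23)
    with pytest.raises(ValueError):
        log10_bf_correlation(0.3, 3)


def test_jarque_bera_moment_oracle_and_errors(rng):
    x = rng.standard_normal(500)
    jb, p = jarque_bera(x)
    n = len(x)
    skew = stats.skew(x)
    kurt = stats.kurtosis(x, fisher=False)
    assert jb == pytest.approx(n / 6 * (skew**2 + (kurt - 3) ** 2 / 4), rel=1e-9)
    assert p > 0.05
    with pytest.raises(ValueError, match="constant"):
        jarque_bera(np.ones(40))
    with pytest.warns(UserWarning, match="asymptotic"):
        jarque_bera(rng.standard_normal(20))
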