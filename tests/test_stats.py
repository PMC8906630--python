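"""Statistical procedures against enumeration and sums-of-squares oracles."""

import itertools
import math

import numpy as np
import numpy.testing as npt
import pytest
from scipy import stats as sps

from dermachroma import stats as dst

# ---------------------------------------------------------------------------
# Oracles


def spearman_rho_oracle(x, y):
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_exact_p_oracle(x, y):
    """Two-sided p by full enumeration of all n! pairings."""
    obs = abs(spearman_rho_oracle(x, y))
    ry = sps.rankdata(y)
    count = total = 0
    for perm in itertools.permutations(sps.rankdata(x)):
        total += 1
        if abs(np.corrcoef(perm, ry)[0, 1]) >= obs - 1e-12:
            count += 1
    return count / total


def wilcoxon_exact_p_oracle(d):
    """Two-sided p by enumeration of all 2^n sign assignments of the
    |difference| ranks (tie-free inputs)."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        w = min(w_plus, n * (n + 1) / 2 - w_plus)
        if w <= w_obs + 1e-12:
            count += 1
    return count / 2**n


def rm_anova_ss_oracle(y):
    """From-scratch two-way within-subject ANOVA with explicit loops;
    returns uncorrected (F, df1, df2, p) per effect."""
    n, a, b = y.shape
    grand = y.mean()
    ss_a = ss_b = ss_ab = ss_as = ss_bs = ss_abs = 0.0
    for i in range(a):
        ss_a += n * b * (y[:, i, :].mean() - grand) ** 2
    for j in range(b):
        ss_b += n * a * (y[:, :, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            ss_ab += n * (y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + grand) ** 2
    for s in range(n):
        for i in range(a):
            ss_as += b * (y[s, i, :].mean() - y[s].mean() - y[:, i, :].mean() + grand) ** 2
        for j in range(b):
            ss_bs += a * (y[s, :, j].mean() - y[s].mean() - y[:, :, j].mean() + grand) ** 2
        for i in range(a):
            for j in range(b):
                ss_abs += (
                    y[s, i, j] - y[s, i, :].mean() - y[s, :, j].mean() - y[:, i, j].mean()
                    + y[s].mean() + y[:, i, :].mean() + y[:, :, j].mean() - grand
                ) ** 2
    out = {}
    for name, ss_eff, ss_err, df1 in [
        ("group", ss_a, ss_as, a - 1),
        ("time", ss_b, ss_bs, b - 1),
        ("group_x_time", ss_ab, ss_abs, (a - 1) * (b - 1)),
    ]:
        df2 = df1 * (n - 1)
        F = (ss_eff / df1) / (ss_err / df2)
        out[name] = (F, df1, df2, float(sps.f.sf(F, df1, df2)))
    return out


# ---------------------------------------------------------------------------
# Bonferroni


@pytest.mark.parametrize("alpha,m,expected", [(0.05, 3, 0.0167), (0.05, 1, 0.05), (0.05, 4, 0.0125)])
def test_bonferroni_alpha(alpha, m, expected):
    assert dst.bonferroni_alpha(alpha, m) == pytest.approx(expected, abs=5e-5)


def test_bonferroni_invalid_m():
    with pytest.raises(ValueError):
        dst.bonferroni_alpha(0.05, 0)


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_monotone_limits():
    assert dst.spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
    assert dst.spearman([1, 2, 3, 4], [40, 30, 20, 10]).rho == pytest.approx(-1.0)


def test_spearman_exact_small_n_matches_enumeration():
    x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
    res = dst.spearman(x, y, method="exact")
    assert res.rho == pytest.approx(spearman_rho_oracle(x, y))  # = 0.8
    assert res.rho == pytest.approx(0.8)
    assert res.p == pytest.approx(spearman_exact_p_oracle(x, y))
    assert res.p == pytest.approx(16 / 120)


def test_spearman_exact_matches_enumeration_random(rng):
    for _ in range(5):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        res = dst.spearman(x, y, method="exact")
        assert res.p == pytest.approx(spearman_exact_p_oracle(x, y), abs=1e-12)


def test_spearman_asymptotic_matches_t_formula(rng):
    x, y = rng.normal(size=20), rng.normal(size=20)
    res = dst.spearman(x, y, method="asymptotic")
    t = res.rho * math.sqrt((20 - 2) / (1 - res.rho**2))
    assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 18))
    ref = sps.spearmanr(x, y)
    assert res.rho == pytest.approx(ref.statistic)
    assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


def test_spearman_invariant_under_monotone_transform(rng):
    x = rng.normal(size=15)
    y = rng.normal(size=15)
    base = dst.spearman(x, y, method="asymptotic")
    for fx, fy in [(np.exp, lambda v: v**3), (lambda v: 2 * v + 1, np.tanh)]:
        r = dst.spearman(fx(x), fy(y), method="asymptotic")
        assert r.rho == pytest.approx(base.rho)
        assert r.p == pytest.approx(base.p)


def test_spearman_constant_vector_errors():
    with pytest.raises(ValueError, match="constant"):
        dst.spearman([1, 1, 1, 1], [1, 2, 3, 4])


def test_spearman_perfect_rho_p_limit():
    res = dst.spearman(np.arange(20.0), np.arange(20.0) ** 3, method="asymptotic")
    assert res.rho == 1.0 and res.p == 0.0


# ---------------------------------------------------------------------------
# Wilcoxon


def test_wilcoxon_all_zero_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        dst.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


def test_wilcoxon_all_positive_exact():
    res = dst.wilcoxon_signed_rank(np.arange(1.0, 7.0))
    assert res.statistic == 0
    assert res.p == pytest.approx(2 / 2**6)
    assert res.n_effective == 6


def test_wilcoxon_significance_flag_at_adjusted_level():
    # p slightly above the 0.0167 Bonferroni level must not flag
    rng = np.random.default_rng(5)
    for _ in range(200):
        d = rng.normal(0.6, 1, size=12)
        res = dst.wilcoxon_signed_rank(d, alpha_adjusted=0.0167)
        assert res.significant == (res.p < 0.0167)
        if 0.0167 < res.p < 0.05:
            assert not res.significant


@pytest.mark.parametrize("n", range(1, 11))
def test_wilcoxon_exact_matches_sign_flip_enumeration(n, rng):
    """Exact p equals full 2^n enumeration for tie-free inputs of
    every effective size up to 10."""
    for _ in range(4):
        d = rng.normal(0.3, 1, size=n)
        while np.unique(np.abs(d)).size < n or (d == 0).any():
            d = rng.normal(0.3, 1, size=n)
        res = dst.wilcoxon_signed_rank(d)
        assert res.p == pytest.approx(wilcoxon_exact_p_oracle(d), abs=1e-12)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(-10, 10, allow_nan=False).filter(lambda v: v != 0),
            min_size=1, max_size=8, unique_by=abs,
        )
    )
    def test_property_wilcoxon_exact_equals_enumeration(diffs):
        """For any tie-free difference vector up to n=8 the exact p
        equals the sign-flip enumeration."""
        res = dst.wilcoxon_signed_rank(np.array(diffs))
        assert res.p == pytest.approx(wilcoxon_exact_p_oracle(diffs), abs=1e-12)

except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


def test_wilcoxon_zero_discard_convention():
    d = np.array([0.0, 0.0, 1.0, 2.0, -3.0])
    res = dst.wilcoxon_signed_rank(d)
    assert res.n_effective == 3


# ---------------------------------------------------------------------------
# RM-ANOVA


def test_rm_anova_flat_data_boundary():
    """Only subject offsets: every within-subject effect has zero
    variance, F = 0 and p = 1."""
    y = np.zeros((6, 2, 4)) + np.arange(6)[:, None, None]
    for res in dst.rm_anova_two_way(y):
        assert res.F == 0.0
        assert res.p == 1.0


def test_rm_anova_matches_ss_oracle_on_fixture():
    """F and p for all three effects match the loop-based
    sums-of-squares oracle on a fixed 5-subject design."""
    rng = np.random.default_rng(2024)
    y = rng.normal(size=(5, 2, 4)) + 0.5 * rng.normal(size=(5, 1, 1))
    oracle = rm_anova_ss_oracle(y)
    results = {r.effect: r for r in dst.rm_anova_two_way(y)}
    assert set(results) == set(oracle)
    for effect, (F, df1, df2, p_unc) in oracle.items():
        r = results[effect]
        assert r.F == pytest.approx(F, rel=1e-10)
        if not r.sphericity_violated:
            assert (r.df1, r.df2) == (df1, df2)
            assert r.p == pytest.approx(p_unc, rel=1e-10)
        else:  # epsilon-scaled F distribution
            assert r.p == pytest.approx(
                float(sps.f.sf(F, r.epsilon_gg * df1, r.epsilon_gg * df2)), rel=1e-10
            )


def test_rm_anova_epsilon_bounds(rng):
    for _ in range(20):
        y = rng.normal(size=(8, 2, 4))
        for r in dst.rm_anova_two_way(y):
            q = 1 if r.effect == "group" else 3
            assert 1 / q - 1e-12 <= r.epsilon_gg <= 1 + 1e-12


def test_rm_anova_two_levels_equals_paired_t_squared(rng):
    y = rng.normal(size=(10, 1, 2))
    res = dst.rm_anova_two_way(y)
    assert len(res) == 1 and res[0].effect == "time"
    t = sps.ttest_rel(y[:, 0, 0], y[:, 0, 1])
    assert res[0].F == pytest.approx(t.statistic**2, rel=1e-10)
    assert res[0].p == pytest.approx(t.pvalue, rel=1e-10)


def test_rm_anova_cross_check_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    import pandas as pd

    y = rng.normal(size=(9, 2, 4)) + rng.normal(size=(9, 1, 1))
    rows = [
        dict(subj=s, group=g, time=t, val=y[s, g, t])
        for s in range(9)
        for g in range(2)
        for t in range(4)
    ]
    aov = pg.rm_anova(
        data=pd.DataFrame(rows), dv="val", within=["group", "time"],
        subject="subj", correction=True, detailed=True,
    ).set_index("Source")
    ours = {r.effect: r for r in dst.rm_anova_two_way(y)}
    for src, effect in [("group", "group"), ("time", "time"), ("group * time", "group_x_time")]:
        assert ours[effect].F == pytest.approx(aov.loc[src, "F"], rel=1e-9)
        assert ours[effect].epsilon_gg == pytest.approx(aov.loc[src, "eps"], rel=1e-9)
        # pingouin reports the uncorrected p unconditionally
        p_unc = float(sps.f.sf(ours[effect].F, *{
            "group": (1, 8), "time": (3, 24), "group_x_time": (3, 24)
        }[effect]))
        assert p_unc == pytest.approx(aov.loc[src, "p_unc"], rel=1e-9)


def test_rm_anova_input_validation():
    with pytest.raises(ValueError, match="3 subjects"):
        dst.rm_anova_two_way(np.zeros((2, 2, 4)))
    bad = np.zeros((4, 2, 4))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="complete"):
        dst.rm_anova_two_way(bad)
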