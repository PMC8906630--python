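"""Statistical procedures for the longitudinal colorimetric analysis.

Three procedures are used downstream:

* a two-way repeated-measures ANOVA (group x time, both within
  subject) with Mauchly's sphericity test and a Greenhouse-Geisser
  correction applied only when sphericity is rejected at 0.05;
* the Wilcoxon signed-rank test for paired irradiated-vs-control
  comparisons, judged against a Bonferroni-adjusted level
  (0.05 / 3 = 0.0167 by default);
* Spearman's rank correlation for dose-response and early-vs-late
  relations.

The ANOVA is computed from its sums-of-squares decomposition directly:
the conditional sphericity correction (per effect, only on rejection)
is part of the procedure under test, so every degree of freedom and
epsilon must be explicit.  Wilcoxon and Spearman delegate the p-value
machinery to scipy while keeping the statistic conventions (min-sum
W, midranks) pinned here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RMAnovaResult",
    "PairedTestResult",
    "CorrelationResult",
    "bonferroni_alpha",
    "spearman",
    "wilcoxon_signed_rank",
    "rm_anova_two_way",
]


@dataclass(frozen=True)
class RMAnovaResult:
    """One within-subject effect from the repeated-measures ANOVA.

    ``df1``/``df2`` are the epsilon-scaled degrees of freedom actually
    used for the p-value; ``epsilon_gg`` is the Greenhouse-Geisser
    estimate (1 when the effect has a single degree of freedom);
    ``sphericity_violated`` records whether Mauchly's test rejected at
    0.05 and hence whether the correction was applied.
    """

    effect: str
    F: float
    df1: float
    df2: float
    epsilon_gg: float
    mauchly_p: float
    p: float
    sphericity_violated: bool


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float  # min of the signed-rank sums
    p: float
    n_effective: int  # pairs remaining after zero differences are dropped
    significant: bool
    alpha_adjusted: float


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison level controlling the family-wise error at
    ``family_alpha`` over ``m`` comparisons."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return family_alpha / m


# ---------------------------------------------------------------------------
# Spearman rank correlation


def _rank_pearson(x: np.ndarray, y: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.mean(axis=axis, keepdims=True)
    y = y - y.mean(axis=axis, keepdims=True)
    num = (x * y).sum(axis=axis)
    den = np.sqrt((x**2).sum(axis=axis) * (y**2).sum(axis=axis))
    return num / den


def spearman(x, y, method: str = "auto") -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive midranks.  ``method`` selects the p-value route:
    ``"asymptotic"`` uses the t approximation
    t = rho * sqrt((n-2) / (1-rho^2)); ``"exact"`` enumerates all n!
    pairings of the rank vectors (feasible for small n); ``"auto"``
    picks exact for n <= 8 and the approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(_rank_pearson(rx, ry))

    if method == "auto":
        method = "exact" if n <= 8 else "asymptotic"
    if method == "exact":
        res = sps.permutation_test(
            (rx,),
            lambda xs, axis=-1: _rank_pearson(xs, ry, axis=axis),
            permutation_type="pairings",
            n_resamples=np.inf,
            alternative="two-sided",
        )
        p = float(res.pvalue)
    elif method == "asymptotic":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(rho=rho, p=min(p, 1.0), n=n)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test


def wilcoxon_signed_rank(a, b=None, alpha_adjusted: float = 0.05) -> PairedTestResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are discarded (Wilcoxon's convention); the
    statistic is the smaller of the positive and negative midrank
    sums.  The p-value is exact (sign-flip enumeration) for up to 15
    tie-free effective pairs and otherwise a normal approximation with
    tie and continuity corrections.  ``significant`` compares p to the
    Bonferroni-adjusted level.
    """
    a = np.asarray(a, dtype=float)
    d = a - np.asarray(b, dtype=float) if b is not None else a
    if d.ndim != 1:
        raise ValueError("paired differences must form a 1-D vector")
    d = d[d != 0]
    n_eff = d.size
    if n_eff == 0:
        raise ValueError("all paired differences are zero; test degenerate")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    has_ties = np.unique(np.abs(d)).size < n_eff
    method = "exact" if (n_eff <= 15 and not has_ties) else "approx"
    if n_eff == 1 and method == "approx":  # pragma: no cover - unreachable
        method = "exact"
    res = sps.wilcoxon(d, alternative="two-sided", correction=True, method=method)
    p = float(res.pvalue)
    return PairedTestResult(
        statistic=w,
        p=p,
        n_effective=n_eff,
        significant=bool(p < alpha_adjusted),
        alpha_adjusted=alpha_adjusted,
    )


# ---------------------------------------------------------------------------
# Two-way repeated-measures ANOVA


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to 1)."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
    return helmert / np.linalg.norm(helmert, axis=1, keepdims=True)


def _mauchly_gg(scores: np.ndarray) -> tuple[float, float]:
    """Mauchly p-value and Greenhouse-Geisser epsilon from per-subject
    orthonormal-contrast scores (n x q)."""
    n, q = scores.shape
    if q == 1:
        return 1.0, 1.0
    centered = scores - scores.mean(axis=0, keepdims=True)
    cov = centered.T @ centered / (n - 1)
    eig = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    tr = eig.sum()
    if tr <= 0:
        return 1.0, 1.0
    eps = tr**2 / (q * (eig**2).sum())
    det = np.prod(eig)
    if det <= 0 or n - 1 < q:
        # singular contrast covariance: sphericity untestable, treat as
        # violated so the conservative correction applies
        return 0.0, float(eps)
    w = det / (tr / q) ** q
    chi2 = -(n - 1 - (2 * q**2 + q + 2) / (6.0 * q)) * np.log(w)
    df = q * (q + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df))
    return p, float(eps)


def _effect_result(
    name: str, ss_eff: float, ss_err: float, df1: int, df2: int, scores: np.ndarray,
    sphericity_alpha: float,
) -> RMAnovaResult:
    ms_eff = ss_eff / df1
    ms_err = ss_err / df2
    F = ms_eff / ms_err if ms_err > 0 else 0.0
    mauchly_p, eps = _mauchly_gg(scores)
    violated = bool(mauchly_p < sphericity_alpha)
    d1, d2 = (eps * df1, eps * df2) if violated else (float(df1), float(df2))
    p = float(sps.f.sf(F, d1, d2)) if ms_err > 0 else 1.0
    return RMAnovaResult(
        effect=name, F=float(F), df1=d1, df2=d2, epsilon_gg=eps,
        mauchly_p=mauchly_p, p=p, sphericity_violated=violated,
    )


def rm_anova_two_way(values, sphericity_alpha: float = 0.05) -> list[RMAnovaResult]:
    """Two-way fully within-subject ANOVA on a (subjects, groups, times)
    array.

    Sums of squares are partitioned with subject, subject x group,
    subject x time and subject x group x time error strata.  For each
    multi-level effect, Mauchly's test runs on the covariance of its
    orthonormal-contrast scores (collapsing over the other factor for
    main effects); when it rejects at ``sphericity_alpha`` the
    Greenhouse-Geisser epsilon scales that effect's degrees of freedom.

    A group axis of length 1 degenerates to the one-way (time only)
    repeated-measures ANOVA.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3:
        raise ValueError("values must have shape (subjects, groups, times)")
    n, a, b = y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(y).any():
        raise ValueError("design must be complete (no missing cells)")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_i = y.mean(axis=(0, 2))
    m_j = y.mean(axis=(0, 1))
    m_si = y.mean(axis=2)
    m_sj = y.mean(axis=1)
    m_ij = y.mean(axis=0)

    ss_total = ((y - grand) ** 2).sum()
    ss_sub = a * b * ((m_s - grand) ** 2).sum()
    ss_a = n * b * ((m_i - grand) ** 2).sum()
    ss_b = n * a * ((m_j - grand) ** 2).sum()
    ss_ab = n * ((m_ij - m_i[:, None] - m_j[None, :] + grand) ** 2).sum()
    ss_as = b * ((m_si - m_s[:, None] - m_i[None, :] + grand) ** 2).sum()
    ss_bs = a * ((m_sj - m_s[:, None] - m_j[None, :] + grand) ** 2).sum()
    ss_abs = ss_total - ss_sub - ss_a - ss_b - ss_ab - ss_as - ss_bs

    results: list[RMAnovaResult] = []
    c_b = _orthonormal_contrasts(b)
    if a > 1:
        c_a = _orthonormal_contrasts(a)
        results.append(
            _effect_result("group", ss_a, ss_as, a - 1, (a - 1) * (n - 1),
                           m_si @ c_a.T, sphericity_alpha)
        )
    results.append(
        _effect_result("time", ss_b, ss_bs, b - 1, (b - 1) * (n - 1),
                       m_sj @ c_b.T, sphericity_alpha)
    )
    if a > 1:
        c_ab = np.kron(c_a, c_b)
        results.append(
            _effect_result(
                "group_x_time", ss_ab, ss_abs, (a - 1) * (b - 1),
                (a - 1) * (b - 1) * (n - 1),
                y.reshape(n, a * b) @ c_ab.T, sphericity_alpha,
            )
        )
    return results
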