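"""Shared statistical primitives: Welch's t, BH FDR, hypergeometric tail.

These are the tests the downstream analyses report: Welch's two-sample t-test
for group mean contrasts (gene density in A vs B compartments, boundary vs
interior), Benjamini-Hochberg FDR control over per-pixel tests, and the
upper-tail hypergeometric enrichment probability (the ``phyper`` convention:
P(X >= k) for k successes among n draws from a population of N containing K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["WelchResult", "welch_ttest", "bh_adjust", "hypergeom_pvalue", "hypergeom_tail_profile"]


@dataclass(frozen=True)
class WelchResult:
    mean1: float
    mean2: float
    n1: int
    n2: int
    t: float
    df: float
    pvalue: float


def welch_ttest(x, y) -> WelchResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    t = (mean(x) - mean(y)) / sqrt(s1^2/n1 + s2^2/n2), with the
    Welch-Satterthwaite degrees of freedom.  The degenerate case of two
    zero-variance groups is defined as t = 0, p = 1 when the means agree and
    t = +/-inf, p = 0 when they differ.  Raises if either group has fewer
    than two observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 observations (got {n1}, {n2})")
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    if se2 == 0:
        if diff == 0:
            return WelchResult(m1, m2, n1, n2, 0.0, float(n1 + n2 - 2), 1.0)
        t = np.inf if diff > 0 else -np.inf
        return WelchResult(m1, m2, n1, n2, float(t), float(n1 + n2 - 2), 0.0)
    t = diff / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(m1), float(m2), n1, n2, float(t), float(df), float(min(p, 1.0)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_tail_profile(N: int, K: int, n: int) -> np.ndarray:
    """Upper-tail probabilities P(X >= k) for every k in 0..min(K, n).

    Computed in log space: the log-pmf over the support is suffix-accumulated
    with log-sum-exp.  Entries at or below the support minimum
    ``max(0, n - (N - K))`` are exactly 1.
    """
    for name, v in (("N", N), ("K", K), ("n", n)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if K > N or n > N:
        raise ValueError(f"require K <= N and n <= N (N={N}, K={K}, n={n})")
    kmax = min(K, n)
    kmin = max(0, n - (N - K))
    ks = np.arange(kmin, kmax + 1)
    logp = sps.hypergeom.logpmf(ks, N, K, n)
    suffix = np.logaddexp.accumulate(logp[::-1])[::-1]
    tail = np.ones(kmax + 1)
    tail[kmin:] = np.minimum(1.0, np.exp(suffix))
    tail[: kmin + 1] = 1.0
    return tail


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), computed in log space.

    X counts class members among ``n`` draws without replacement from a
    population of ``N`` containing ``K`` class members.  ``k = 0`` returns
    exactly 1.  Raises on infeasible arguments (``k > min(K, n)`` or
    inconsistent sizes).
    """
    if k < 0 or int(k) != k:
        raise ValueError(f"k must be a non-negative integer, got {k}")
    kmax = min(K, n)
    if k > kmax:
        raise ValueError(f"infeasible overlap k={k} > min(K, n)={kmax}")
    return float(hypergeom_tail_profile(N, K, n)[k])
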