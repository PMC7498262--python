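"""Exact and asymptotic statistical kernels shared across the pipeline.

The exact tests (hypergeometric tail, Fisher) are evaluated in log-space
with ``gammaln`` so that tables with large margins do not overflow; the
asymptotic tails (chi-square, Kolmogorov, Student t) come from scipy.
All functions are pure and perform no I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, kolmogorov, logsumexp
from scipy.stats import chi2 as _chi2
from scipy.stats import t as _t_dist

__all__ = [
    "ContingencyTable2x2",
    "TTestResult",
    "hypergeom_upper_tail",
    "fisher_exact",
    "ks_two_sample",
    "chi_square_gof",
    "bh_fdr",
    "t_two_sample",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts ``a, b`` (first row) and ``c, d`` (second row), all >= 0."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
        if self.a + self.b + self.c + self.d <= 0:
            raise ValueError("contingency table must have positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        """(a*d)/(b*c); ``inf`` when b*c == 0 and a*d > 0, ``nan`` for 0/0."""
        num, den = self.a * self.d, self.b * self.c
        if den == 0:
            return math.nan if num == 0 else math.inf
        return num / den


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _hypergeom_log_pmf(N: int, K: int, n: int, k) -> np.ndarray:
    k = np.asarray(k)
    return _log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability ``P(X >= k)`` for ``X ~ Hypergeom(N, K, n)``.

    ``N`` population size, ``K`` successes in the population, ``n`` draws.
    Computed by a log-space sum over the support, exact to ~1e-14.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError(f"K and n must not exceed N (N={N}, K={K}, n={n})")
    k_min = max(0, n + K - N)
    k_max = min(K, n)
    if k > k_max:
        raise ValueError(f"k={k} exceeds max attainable overlap {k_max}")
    if k <= k_min:
        return 1.0
    ks = np.arange(k, k_max + 1)
    log_p = _hypergeom_log_pmf(N, K, n, ks)
    return float(min(1.0, math.exp(logsumexp(log_p))))


def fisher_exact(table: ContingencyTable2x2, alternative: str = "greater") -> float:
    """Fisher's exact test p-value on a 2x2 table.

    ``greater`` is the hypergeometric upper tail of cell ``a`` given the
    margins; ``two_sided`` sums probabilities of all tables (same margins)
    no more probable than the observed one, the standard convention.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    N = table.total
    K = table.a + table.b  # row-1 margin
    n = table.a + table.c  # column-1 margin
    if alternative == "greater":
        return hypergeom_upper_tail(N, K, n, table.a)
    k_min = max(0, n + K - N)
    k_max = min(K, n)
    ks = np.arange(k_min, k_max + 1)
    log_p = _hypergeom_log_pmf(N, K, n, ks)
    log_obs = float(_hypergeom_log_pmf(N, K, n, np.array([table.a]))[0])
    # relative tolerance guards against log-space ties being split by rounding
    keep = log_p <= log_obs + 1e-7
    return float(min(1.0, math.exp(logsumexp(log_p[keep]))))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    ``D`` is the exact supremum distance between the two empirical CDFs,
    evaluated at every pooled data point (ties handled by evaluating both
    ECDFs at the same points). The p-value uses the asymptotic Kolmogorov
    distribution with the effective sample size ``n*m/(n+m)``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    if d == 0.0:
        return 0.0, 1.0
    en = x.size * y.size / (x.size + y.size)
    p = float(kolmogorov(math.sqrt(en) * d))
    return d, min(1.0, max(p, 0.0))


def chi_square_gof(
    observed: Sequence[float], expected_proportions: Sequence[float]
) -> tuple[float, float]:
    """Chi-square goodness of fit of label counts against expected proportions.

    Returns ``(statistic, p)`` with ``df = len(observed) - 1``. Expected
    proportions must sum to 1 and every expected count must be positive.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected_proportions must have equal length")
    if not math.isclose(props.sum(), 1.0, abs_tol=1e-8):
        raise ValueError(f"expected proportions sum to {props.sum()}, not 1")
    expected = obs.sum() * props
    if np.any(expected <= 0):
        raise ValueError(
            "zero expected count for a label; merge rare labels before testing"
        )
    stat = float(np.sum((obs - expected) ** 2 / expected))
    p = 1.0 if stat == 0.0 else float(_chi2.sf(stat, df=obs.size - 1))
    return stat, min(1.0, max(p, 0.0))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def t_two_sample(
    x: Sequence[float], y: Sequence[float], equal_variance: bool = True
) -> TTestResult:
    """Two-sample Student t-test, two-sided.

    The default is the classical pooled-variance test; ``equal_variance=False``
    gives Welch's variant with Satterthwaite degrees of freedom. A zero
    standard error is reported with ``degenerate=True``: t = 0, p = 1 when the
    means agree, otherwise t = ±inf, p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    nx, ny = x.size, y.size
    mx, my = float(x.mean()), float(y.mean())
    vx, vy = float(x.var(ddof=1)), float(y.var(ddof=1))
    if equal_variance:
        df = float(nx + ny - 2)
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = math.sqrt(pooled * (1 / nx + 1 / ny))
    else:
        se2x, se2y = vx / nx, vy / ny
        se = math.sqrt(se2x + se2y)
        if se > 0:
            df = (se2x + se2y) ** 2 / (
                se2x**2 / (nx - 1) + se2y**2 / (ny - 1)
            )
        else:
            df = float(nx + ny - 2)
    diff = mx - my
    if se == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0, degenerate=True)
    t = diff / se
    p = float(2.0 * _t_dist.sf(abs(t), df))
    return TTestResult(t, df, min(1.0, p), degenerate=False)
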