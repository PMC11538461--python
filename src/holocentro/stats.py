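"""Statistical primitives used throughout the pipeline.

Mann–Whitney U (exact enumeration for small untied samples, normal
approximation with tie and continuity corrections otherwise), Spearman rank
correlation with a t-approximation p-value, Benjamini–Hochberg step-up
adjustment, and empirical percentile ranks with midrank tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "spearman_rho",
    "bh_adjust",
    "empirical_percentile",
]

_ALTERNATIVES = {"two-sided", "greater", "less"}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alternative: str
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")


# -- Mann-Whitney U ----------------------------------------------------------


@lru_cache(maxsize=None)
def _u_count(n: int, m: int, u: int) -> int:
    """Number of rank arrangements with statistic exactly u, no ties.

    Classic recursion on the last-ranked observation:
    c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u).
    """
    if u < 0 or u > n * m:
        return 0
    if n == 0 or m == 0:
        return 1 if u == 0 else 0
    return _u_count(n - 1, m, u - m) + _u_count(n, m - 1, u)


def _exact_sf(u: float, n: int, m: int) -> float:
    """P(U >= u) under the exact null distribution (no ties)."""
    from math import comb

    k = int(np.ceil(u - 1e-9))
    total = comb(n + m, n)
    return sum(_u_count(n, m, v) for v in range(k, n * m + 1)) / total


def mann_whitney_u(
    x, y, alternative: str = "two-sided", exact_limit: int = 100
) -> TestResult:
    """Mann–Whitney U test comparing two independent samples.

    U is the statistic for the first sample (count of (x, y) pairs with
    x > y, ties counting one half). The exact null distribution is
    enumerated when ``len(x) * len(y) <= exact_limit`` and the pooled data
    carry no ties; otherwise the normal approximation with tie and
    continuity corrections is used.

    ``alternative='greater'`` tests whether x tends to exceed y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_x = ranks[:n].sum()
    u_x = r_x - n * (n + 1) / 2.0  # pairs where x beats y (ties half)
    u_y = n * m - u_x

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if not has_ties and n * m <= exact_limit:
        method = "exact"
        if alternative == "greater":
            p = _exact_sf(u_x, n, m)
        elif alternative == "less":
            p = _exact_sf(u_y, m, n)
        else:
            p = min(1.0, 2.0 * _exact_sf(max(u_x, u_y), n, m))
    else:
        method = "normal-approximation"
        mu = n * m / 2.0
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (
            (n + m) * (n + m - 1)
        )
        sigma2 = n * m / 12.0 * ((n + m + 1) - tie_term)
        if sigma2 <= 0:  # all observations identical
            return TestResult(u_x, 1.0, alternative, method)
        sigma = np.sqrt(sigma2)

        def sf(u: float) -> float:
            return float(norm.sf((u - mu - 0.5) / sigma))

        if alternative == "greater":
            p = sf(u_x)
        elif alternative == "less":
            p = sf(u_y)
        else:
            p = min(1.0, 2.0 * sf(max(u_x, u_y)))
    return TestResult(float(u_x), float(min(max(p, 0.0), 1.0)), alternative, method)


# -- Spearman ----------------------------------------------------------------


def spearman_rho(x, y, alternative: str = "two-sided") -> TestResult:
    """Spearman rank correlation: Pearson correlation of midranks.

    The p-value uses the t-approximation with n−2 degrees of freedom.
    Constant input vectors leave the correlation undefined and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    rx, ry = rankdata(x), rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(
        (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
    )
    rho = min(1.0, max(-1.0, rho))
    n = x.size
    if abs(rho) == 1.0:
        t_stat = np.inf if rho > 0 else -np.inf
        p_two = 0.0
    else:
        t_stat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p_two = 2.0 * float(t_dist.sf(abs(t_stat), df=n - 2))
    if alternative == "two-sided":
        p = min(1.0, p_two)
    elif alternative == "greater":
        p = float(t_dist.sf(t_stat, df=n - 2)) if np.isfinite(t_stat) else (
            0.0 if rho > 0 else 1.0
        )
    else:
        p = float(t_dist.cdf(t_stat, df=n - 2)) if np.isfinite(t_stat) else (
            0.0 if rho < 0 else 1.0
        )
    return TestResult(rho, p, alternative, "t-approximation")


# -- multiple testing --------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    adjusted(i) = min_{j >= i} p(j) * m / j over the sorted p-values,
    clipped to 1; returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a vector")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def empirical_percentile(real_value: float, simulated) -> float:
    """Midrank percentile of ``real_value`` within ``simulated``.

    percentile = 100 * (#{sim < real} + 0.5 * #{sim == real}) / n.
    """
    sim = np.asarray(simulated, dtype=float)
    if sim.size == 0:
        raise ValueError("simulated values must be non-empty")
    below = float((sim < real_value).sum())
    equal = float((sim == real_value).sum())
    return 100.0 * (below + 0.5 * equal) / sim.size
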