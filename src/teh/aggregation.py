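"""Merging K dependent per-split p values into one valid aggregate p value.

Repeated random data-splitting yields K p values {p_1, ..., p_K} that are
individually valid but mutually dependent (every split reuses the same
subjects).  Two merging rules are provided, both of which keep the type I
error at level alpha regardless of that dependence:

fixed-gamma rule
    p_agg = min(1, Quantile_gamma({p_i / gamma})), with gamma chosen in the
    analysis plan.  For gamma = 0.5 this is min(1, median of the doubled
    p values).

adaptive rule
    p_agg = min over gamma in [alpha, 1] of
            min(1, (1 - log alpha) * Q_gamma({p_i})),
    where Q_gamma is the fixed-gamma quantity above and the factor
    (1 - log alpha), natural log, pays for searching over gamma.

Quantile convention: the inverse empirical CDF, i.e. the smallest order
statistic whose ECDF reaches gamma (`sorted_p[ceil(gamma*K) - 1]`).  The
gamma search is exact: Q_gamma is piecewise in gamma with breakpoints at
the order-statistic levels j/K, and on each piece it is decreasing in
gamma, so minimising over {alpha} U {j/K : j >= ceil(alpha*K)} attains the
continuum minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AggregateResult",
    "quantile_scaled",
    "aggregate_fixed_gamma",
    "aggregate_adaptive",
    "boundary_curve",
    "ecdf_crosses_boundary",
]


@dataclass
class AggregateResult:
    """K per-split p values and their merged aggregate.

    ``trace[k-1]`` is the aggregate recomputed from the first k p values
    with the same method and parameters; its last entry equals
    ``p_aggregate``.  Used as a stabilisation diagnostic in K.
    """

    p_values: np.ndarray
    p_aggregate: float
    method: str
    alpha: float | None = None
    gamma: float | None = None
    trace: np.ndarray = field(default=None)

    def __post_init__(self):
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.trace is not None:
            self.trace = np.asarray(self.trace, dtype=float)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "p_values": self.p_values.tolist(),
            "p_aggregate": float(self.p_aggregate),
            "trace": self.trace.tolist() if self.trace is not None else None,
        }


def _check_pvalues(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d collection")
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return p


def _quantile_scaled_sorted(sorted_p: np.ndarray, gamma: float) -> float:
    k = sorted_p.size
    j = math.ceil(gamma * k)
    j = min(max(j, 1), k)
    return min(1.0, sorted_p[j - 1] / gamma)


def quantile_scaled(p_values, gamma: float) -> float:
    """min(1, Quantile_gamma({p_i / gamma})) with the inverse-ECDF quantile."""
    p = _check_pvalues(p_values)
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie strictly inside (0, 1)")
    return _quantile_scaled_sorted(np.sort(p), gamma)


def _adaptive_sorted(sorted_p: np.ndarray, alpha: float) -> float:
    """Exact minimisation of (1 - ln alpha) * Q_gamma over gamma in [alpha, 1]."""
    k = sorted_p.size
    j_min = min(max(math.ceil(alpha * k), 1), k)
    js = np.arange(j_min, k + 1)
    q = np.minimum(1.0, sorted_p[js - 1] / (js / k))
    best = q.min()
    # left endpoint gamma = alpha shares the order statistic j_min
    best = min(best, min(1.0, sorted_p[j_min - 1] / alpha))
    return min(1.0, (1.0 - math.log(alpha)) * best)


def aggregate_fixed_gamma(p_values, gamma: float) -> AggregateResult:
    """Merge p values with the fixed-gamma quantile rule."""
    p = _check_pvalues(p_values)
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie strictly inside (0, 1)")
    trace = np.empty(p.size)
    for k in range(1, p.size + 1):
        trace[k - 1] = _quantile_scaled_sorted(np.sort(p[:k]), gamma)
    return AggregateResult(
        p_values=p,
        p_aggregate=float(trace[-1]),
        method="fixed_gamma",
        gamma=gamma,
        trace=trace,
    )


def aggregate_adaptive(p_values, alpha: float = 0.05) -> AggregateResult:
    """Merge p values with the adaptive gamma-sweep rule at level ``alpha``."""
    p = _check_pvalues(p_values)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    trace = np.empty(p.size)
    for k in range(1, p.size + 1):
        trace[k - 1] = _adaptive_sorted(np.sort(p[:k]), alpha)
    return AggregateResult(
        p_values=p,
        p_aggregate=float(trace[-1]),
        method="adaptive",
        alpha=alpha,
        trace=trace,
    )


def boundary_curve(alpha: float, grid: int = 200) -> np.ndarray:
    """Rejection boundary for the p-value ECDF under the adaptive rule.

    Returns the (grid, 2) array of points
    ``(gamma * alpha / (1 - ln alpha), gamma)`` for gamma in [alpha, 1]:
    the adaptive aggregate is <= alpha exactly when the empirical CDF of
    the p values touches or crosses above this segment.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    if grid < 2:
        raise ValueError("grid must be >= 2")
    gammas = np.linspace(alpha, 1.0, grid)
    xs = gammas * alpha / (1.0 - math.log(alpha))
    return np.column_stack([xs, gammas])


def ecdf_crosses_boundary(p_values, alpha: float) -> bool:
    """Does the ECDF of the p values touch/cross above the boundary curve?

    Checked at the ECDF jump points: a crossing occurs iff some order
    statistic p_(j) with j >= ceil(alpha*K) satisfies
    p_(j) <= (j/K) * alpha / (1 - ln alpha).  Equivalent to
    ``aggregate_adaptive(p_values, alpha).p_aggregate <= alpha``.
    """
    p = np.sort(_check_pvalues(p_values))
    k = p.size
    j_min = min(max(math.ceil(alpha * k), 1), k)
    js = np.arange(j_min, k + 1)
    thresh = (js / k) * alpha / (1.0 - math.log(alpha))
    return bool(np.any(p[js - 1] <= thresh))
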