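"""Closed-form resource-utilization analysis.

When every individual independently adopts the behavior subset that best
fills its budget, the achievable spending levels are the distinct subset
sums of the behavior costs not exceeding 1 — the *full utilization points*
``mu_1 < ... < mu_n``.  With resources uniform on (0, 1), an individual
with resource in ``[mu_i, mu_{i+1})`` spends exactly ``mu_i``, which gives
the expected utilization in closed form:

    U(mu) = 2 (mu_1 mu_2 + ... + mu_{n-1} mu_n + mu_n)
            - 2 (mu_1^2 + ... + mu_n^2)

Maximizing over point placements yields uniformly spaced points
``mu_i = i / (n + 1)`` with utilization ``n / (n + 1)``: the cheapest way
to raise network efficiency is to add a low-cost behavior that refines the
grid of achievable sums.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .errors import InvalidParameterError
from .model_core import BehaviorSet

__all__ = ["utilization_points", "max_utilization", "optimal_points"]

_MERGE_TOL = 1e-12


def utilization_points(behaviors: BehaviorSet) -> np.ndarray:
    """Sorted distinct nonzero subset-sums of the behavior costs, capped at 1."""
    costs = behaviors.costs
    sums = set()
    for m in range(1, len(costs) + 1):
        for combo in combinations(costs, m):
            s = float(np.sum(combo))
            if s <= 1.0 + _MERGE_TOL:
                sums.add(min(s, 1.0))
    pts = np.array(sorted(sums))
    # merge float near-collisions such as 0.2 + 0.5 vs 0.7
    keep = [pts[0]] if len(pts) else []
    for p in pts[1:]:
        if p - keep[-1] > _MERGE_TOL:
            keep.append(p)
    return np.array(keep)


def max_utilization(points) -> float:
    """Expected utilization for utilization points ``mu`` under r ~ U(0,1).

    Evaluates ``2(sum mu_i mu_{i+1} + mu_n) - 2 sum mu_i^2``, the ratio of
    the piecewise-constant spend integral to the expected resource 1/2.
    """
    mu = np.asarray(points, dtype=float)
    if mu.ndim != 1 or len(mu) == 0:
        raise InvalidParameterError("need at least one utilization point")
    if np.any(np.diff(mu) <= 0) or mu[0] <= 0 or mu[-1] > 1:
        raise InvalidParameterError("points must be strictly increasing in (0, 1]")
    return float(2.0 * (np.sum(mu[:-1] * mu[1:]) + mu[-1]) - 2.0 * np.sum(mu**2))


def optimal_points(n: int):
    """Uniformly spaced points i/(n+1) and their utilization n/(n+1).

    This placement is the stationary (and maximal) configuration of
    ``max_utilization`` over all n-point sets.
    """
    if n < 1:
        raise InvalidParameterError(f"need n >= 1 points, got {n}")
    pts = np.arange(1, n + 1) / (n + 1)
    return pts, n / (n + 1)
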