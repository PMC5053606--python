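"""Live-edge reformulation of the sticky diffusion process.

Before any diffusion, each node ``v`` draws one incoming edge per behavior
it could ever afford (``kappa(v)`` slots, sampled with replacement): slot
``j`` picks neighbor ``w`` with probability ``b_{v,w} = 1/|N(v)|``.  During
the process, behavior ``j`` becomes a candidate at ``v`` only when the
slot-``j`` live neighbor adopted ``j`` in a previous epoch; adoption is
still knapsack-constrained and sticky.

Marginalized over the random edge choices this process generates the same
distribution of active sets as the sticky threshold dynamics, and for a
*fixed* edge choice the total participation is a coverage function of the
seed set — monotone and submodular — which is what makes greedy seed
selection a (1 - 1/e)-approximation.  The module therefore doubles as an
independent oracle for the sticky model in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from ._engine import COST_TOL, GraphArrays
from .model_core import BehaviorSet, Endowments, RunResult, kappa
from .model_core import _seed_arrays

__all__ = [
    "LiveEdgeSample",
    "sample_live_edges",
    "run_live_edge_process",
    "total_participation_given_sample",
]


@dataclass
class LiveEdgeSample:
    """Chosen in-neighbor per (node, behavior slot); -1 marks no live edge."""

    order: tuple
    choices: np.ndarray  # (n, k) int; choices[v, j] valid only for j < kappa(v)

    def slots(self, v_index: int, kap: int):
        return [int(c) if c >= 0 else None for c in self.choices[v_index, :kap]]


def sample_live_edges(G, endow: Endowments, behaviors: BehaviorSet,
                      rng_seed) -> LiveEdgeSample:
    """Draw one live in-edge per affordable behavior for every node.

    kappa(v) is computed from the original r(v).  With uniform weights
    1/|N(v)| summing to one, the "no edge" branch only occurs for isolated
    nodes.  Slots for behaviors the node can never afford are set to -1.
    """
    ga = G if isinstance(G, GraphArrays) else GraphArrays.from_graph(G)
    rng = np.random.default_rng(rng_seed)
    n, k = ga.n, behaviors.k
    choices = np.full((n, k), -1, dtype=np.int64)
    for vi in range(n):
        kap = kappa(behaviors, endow.resource[vi])
        if kap == 0:
            continue
        nbrs = ga.neighbors(vi)
        if len(nbrs) == 0:
            continue  # isolated: no edge with probability 1
        choices[vi, :kap] = rng.choice(nbrs, size=kap, replace=True)
    return LiveEdgeSample(ga.order, choices)


def run_live_edge_process(G, endow: Endowments, behaviors: BehaviorSet,
                          sample: LiveEdgeSample, seeds, w: float = 0.5,
                          return_adopted: bool = False):
    """Deterministic sticky diffusion driven by a fixed live-edge choice.

    Candidacy for behavior j at v requires v's slot-j live neighbor to have
    adopted j by the previous epoch; payoffs use the full-neighborhood
    social signal, matching the threshold dynamics.
    """
    ga = G if isinstance(G, GraphArrays) else GraphArrays.from_graph(G)
    pinned, r_eff = _seed_arrays(seeds, ga, behaviors, endow.resource)
    c, u = behaviors.costs, behaviors.utilities
    n, k = ga.n, behaviors.k
    choices = sample.choices
    has_edge = choices >= 0
    safe = np.where(has_edge, choices, 0)

    A = pinned.copy()
    s = A @ c
    epochs = 0
    for _ in range(n * k + 1):
        live_active = has_edge & A[safe, np.arange(k)[None, :]]
        resid = r_eff - s
        cand = live_active & ~A & (c <= resid[:, None] + COST_TOL)
        if not cand.any():
            break
        L = _engine.propagate(ga.weights, A)
        pay = w * u + (1.0 - w) * L
        chosen = _engine.best_subsets(pay, _engine.to_bitmask(cand), resid, c)
        if not chosen.any():
            break
        A |= chosen
        s = s + chosen @ c
        epochs += 1

    total_r = float(r_eff.sum())
    result = RunResult(
        participation=int(A.any(axis=1).sum()),
        adoption=int(A.sum()),
        utilization=float(s.sum() / total_r) if total_r > 0 else 0.0,
        epochs_run=epochs,
        converged=True,
    )
    return (result, A) if return_adopted else result


def total_participation_given_sample(G, endow, behaviors, sample, seeds,
                                     w: float = 0.5) -> int:
    """Realized participation sigma'_X(S) for one fixed live-edge choice X."""
    return run_live_edge_process(G, endow, behaviors, sample, seeds, w).participation
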