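"""Multiple-behavior adoption dynamics under resource constraints.

The model: ``k`` behaviors, each with an intrinsic cost ``c_i`` and utility
``u_i`` in [0, 1], spread over an undirected social graph.  Every individual
``v`` has a fixed resource ``r(v)`` and a private threshold ``theta_i(v)``
per behavior, both drawn i.i.d. from U(0, 1).  A neighbor exerts influence
weight ``1/|N(v)|``, so the social signal for behavior ``i`` is

    l_i(v) = sum_{w in N(v), w adopted i} 1 / |N(v)|

and the payoff of adopting ``i`` is ``p_i(v) = w*u_i + (1-w)*l_i(v)``.
Behavior ``j`` is a *candidate* when its signal meets the threshold
(``l_j >= theta_j``) and the node can afford it; the node then adopts the
payoff-maximizing subset of candidates whose total cost fits its budget
(an exact knapsack, enumerated since ``k`` is small).

Two synchronous-epoch dynamics are provided:

* ``sticky`` — progressive adoption; adopted behaviors are never dropped
  and each adoption reduces the remaining budget ``r(v) - s(v)``;
* ``reevaluate`` — every epoch each node re-solves its knapsack over all
  eligible behaviors (already-adopted behaviors stay eligible without
  re-passing the threshold test; seed-pinned behaviors are never dropped),
  so nodes can realign with their neighborhood over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import _engine
from ._engine import COST_TOL, GraphArrays
from .errors import InvalidParameterError

__all__ = [
    "BehaviorSet",
    "Endowments",
    "DiffusionState",
    "RunResult",
    "sample_endowments",
    "social_signal",
    "payoff",
    "kappa",
    "candidate_set",
    "knapsack_select",
    "run_diffusion",
]


@dataclass(frozen=True)
class BehaviorSet:
    """The ``k`` behaviors, index-sorted by non-decreasing cost."""

    costs: np.ndarray
    utilities: np.ndarray

    def __post_init__(self):
        costs = np.asarray(self.costs, dtype=float)
        utils = np.asarray(self.utilities, dtype=float)
        object.__setattr__(self, "costs", costs)
        object.__setattr__(self, "utilities", utils)
        if costs.ndim != 1 or len(costs) < 1 or len(costs) != len(utils):
            raise InvalidParameterError("need one cost and one utility per behavior")
        if np.any(costs < 0) or np.any(costs > 1) or np.any(utils < 0) or np.any(utils > 1):
            raise InvalidParameterError("costs and utilities must lie in [0, 1]")
        if np.any(np.diff(costs) < 0):
            raise InvalidParameterError("behaviors must be indexed in ascending cost order")

    @property
    def k(self) -> int:
        return len(self.costs)

    @classmethod
    def from_pairs(cls, pairs) -> "BehaviorSet":
        """Build from an iterable of (cost, utility) pairs (or mappings)."""
        costs, utils = [], []
        for p in pairs:
            if isinstance(p, dict):
                costs.append(p["cost"])
                utils.append(p["utility"])
            else:
                c, u = p
                costs.append(c)
                utils.append(u)
        order = np.argsort(costs, kind="stable")
        return cls(np.asarray(costs)[order], np.asarray(utils)[order])

    @classmethod
    def proportional(cls, costs) -> "BehaviorSet":
        """Behaviors whose utility equals their cost (u_i = c_i)."""
        c = np.sort(np.asarray(costs, dtype=float))
        return cls(c, c.copy())

    @classmethod
    def from_file(cls, path) -> "BehaviorSet":
        """Load a behavior specification (YAML or JSON list of
        ``{cost, utility}`` mappings)."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, dict):
            data = data["behaviors"]
        return cls.from_pairs(data)


@dataclass
class Endowments:
    """Per-node resources and per-(node, behavior) adoption thresholds."""

    resource: np.ndarray  # (n,)
    thresholds: np.ndarray  # (n, k)

    def __post_init__(self):
        self.resource = np.asarray(self.resource, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.shape[0] != self.resource.shape[0]:
            raise InvalidParameterError("thresholds and resource disagree on node count")

    @property
    def n(self) -> int:
        return len(self.resource)

    @property
    def k(self) -> int:
        return self.thresholds.shape[1]

    def copy(self) -> "Endowments":
        return Endowments(self.resource.copy(), self.thresholds.copy())


def sample_endowments(G: nx.Graph, k: int, rng_seed) -> Endowments:
    """Draw r(v) ~ U(0,1) and theta_i(v) ~ U(0,1), i.i.d., aligned to node order."""
    if k < 1:
        raise InvalidParameterError(f"need k >= 1 behaviors, got {k}")
    rng = np.random.default_rng(rng_seed)
    n = G.number_of_nodes()
    return Endowments(rng.random(n), rng.random((n, k)))


@dataclass
class DiffusionState:
    """Snapshot of the network state at some epoch."""

    order: tuple  # node identifiers, defining row order
    adopted: np.ndarray  # (n, k) bool
    spent: np.ndarray  # (n,) float, sum of adopted costs
    pinned: np.ndarray  # (n, k) bool, seed-assigned behaviors
    epoch: int = 0

    def adopted_set(self, v) -> set:
        """Behavior indices adopted by node ``v``."""
        return set(int(i) for i in np.nonzero(self.adopted[self.order.index(v)])[0])


@dataclass
class RunResult:
    """Final-state metrics of one diffusion run."""

    participation: int
    adoption: int
    utilization: float
    epochs_run: int
    converged: bool


def social_signal(G: nx.Graph, state: DiffusionState, v, i: int) -> float:
    """l_i(v): influence-weight mass of v's neighbors that adopted behavior i."""
    deg = G.degree(v)
    if deg == 0:
        return 0.0
    idx = {node: j for j, node in enumerate(state.order)}
    hits = sum(1 for u in G.neighbors(v) if state.adopted[idx[u], i])
    return hits / deg


def payoff(behaviors: BehaviorSet, i: int, l: float, w: float) -> float:
    """p_i = w*u_i + (1-w)*l, the intent/social-signal blend."""
    return w * float(behaviors.utilities[i]) + (1.0 - w) * l


def kappa(behaviors: BehaviorSet, r: float) -> int:
    """Number of behaviors individually affordable with resource ``r``.

    Equals the largest (1-based) index j with c_j <= r; 0 when none fits.
    """
    return int(np.searchsorted(behaviors.costs, r + COST_TOL, side="right"))


def candidate_set(G, state: DiffusionState, endow: Endowments,
                  behaviors: BehaviorSet, v, budget: float) -> set:
    """Behaviors whose signal meets the threshold and whose cost fits ``budget``."""
    idx = {node: j for j, node in enumerate(state.order)}
    vi = idx[v]
    out = set()
    for i in range(behaviors.k):
        if state.adopted[vi, i]:
            continue
        l = social_signal(G, state, v, i)
        if l >= endow.thresholds[vi, i] and behaviors.costs[i] <= budget + COST_TOL:
            out.add(i)
    return out


def knapsack_select(candidates, payoffs, behaviors: BehaviorSet, budget: float) -> set:
    """Exhaustive knapsack over candidate behaviors.

    Returns the feasible subset with maximal total payoff; ties broken by
    lower total cost, then lexicographically smallest index set.
    """
    candmask = 0
    for i in candidates:
        candmask |= 1 << int(i)
    pay = np.zeros(behaviors.k)
    for i in candidates:
        pay[int(i)] = payoffs[int(i)]
    chosen = _engine.best_subsets(
        pay[None, :], np.array([candmask]), np.array([float(budget)]), behaviors.costs
    )[0]
    return set(int(i) for i in np.nonzero(chosen)[0])


def _seed_arrays(seeds, ga: GraphArrays, behaviors: BehaviorSet, resource):
    """Translate a SeedAssignment into epoch-0 masks and the post-top-up resource."""
    n, k = ga.n, behaviors.k
    pinned = np.zeros((n, k), dtype=bool)
    r_eff = np.asarray(resource, dtype=float).copy()
    if seeds is not None:
        for i, nodes in enumerate(seeds.seed_sets):
            for v in nodes:
                pinned[ga.index[v], i] = True
        for v, extra in seeds.topped_up.items():
            r_eff[ga.index[v]] += extra
    need = pinned @ behaviors.costs
    short = need > r_eff + COST_TOL
    if np.any(short):
        bad = [ga.order[i] for i in np.nonzero(short)[0]]
        raise InvalidParameterError(
            f"seeds cannot afford their pinned behaviors (missing top-up): {bad[:5]}"
        )
    return pinned, r_eff


def run_diffusion(G, endow: Endowments, behaviors: BehaviorSet, seeds,
                  w: float = 0.5, mode: str = "reevaluate",
                  max_epochs: int = 1000):
    """Run the diffusion to quiescence from a seed assignment.

    Epoch 0 installs each seed's pinned behaviors and charges their cost;
    later epochs update all nodes synchronously from the previous state.
    Returns ``(RunResult, DiffusionState)``.  In ``reevaluate`` mode the
    run may hit ``max_epochs`` without a fixed point, in which case
    ``converged`` is False (metrics are still reported from the last state).
    """
    ga = G if isinstance(G, GraphArrays) else GraphArrays.from_graph(G)
    pinned, r_eff = _seed_arrays(seeds, ga, behaviors, endow.resource)
    c, u = behaviors.costs, behaviors.utilities
    if mode == "sticky":
        A, s, epochs = _engine.run_sticky(
            ga, c, u, w, r_eff, endow.thresholds, pinned, max_epochs)
        converged = True
    elif mode == "reevaluate":
        A, s, epochs, converged = _engine.run_reevaluate(
            ga, c, u, w, r_eff, endow.thresholds, pinned,
            _engine.to_bitmask(pinned), max_epochs)
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    total_r = float(r_eff.sum())
    state = DiffusionState(ga.order, A, s, pinned, epochs)
    result = RunResult(
        participation=int(A.any(axis=1).sum()),
        adoption=int(A.sum()),
        utilization=float(s.sum() / total_r) if total_r > 0 else 0.0,
        epochs_run=epochs,
        converged=converged,
    )
    return result, state
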