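"""Seed-selection algorithms and behavior-distribution strategies.

A *seed assignment* designates early adopters: per behavior ``i`` a set of
nodes that pin behavior ``i`` at epoch 0.  Selection algorithms come in four
variants combining two axes:

* ``S`` / ``M`` — each node is a seed for a single behavior, or may carry
  multiple behaviors;
* ``T`` / ``NT`` — a seed short of resource is topped up to the cost of its
  assigned behaviors (``r(v) := c_j`` when ``r(v) <= c_j``), or only
  affordable assignments are allowed.

Selection heuristics, from cheapest to most expensive:

* random baseline;
* naive degree ranking with random / top-up / knapsack behavior assignment;
* degree-and-resource ranking on ``d_i(v)`` = number of neighbors able to
  afford behavior ``i``;
* Constrained Social Influence Weight (CIW)
  ``e_i(v) = 1 + sum_{u in N(v), r(u) >= c_i} 1/|N(u)|``, used either as a
  static ranking or in a max-margin hill climb that discounts the
  contribution of already-selected seeds;
* incremental Expected Immediate Adoption (EIA), committing at each step
  the (behavior, node) pair with the largest exact one-step expected
  adoption gain;
* the simulation-based greedy approximation, which maximizes Monte-Carlo
  estimated total participation of the sticky dynamics and inherits the
  (1 - 1/e) guarantee from submodularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from ._engine import COST_TOL, GraphArrays
from .errors import InfeasibleSeedingError, InvalidParameterError
from .model_core import BehaviorSet, Endowments

__all__ = [
    "SeedAssignment",
    "distribute_behaviors",
    "select_random",
    "select_naive_degree",
    "select_degree_resource_ranked",
    "ciw",
    "select_ciw_ranked",
    "select_ciw_max_margin",
    "compute_ia",
    "select_eia",
    "select_greedy_kkt",
]

VARIANTS = ("S-T", "S-NT", "M-T", "M-NT")


@dataclass
class SeedAssignment:
    """Per-behavior seed sets plus top-up bookkeeping."""

    seed_sets: list  # list (length k) of lists of node identifiers
    topped_up: dict = field(default_factory=dict)  # node -> resource added
    variant: str = "S-T"

    @property
    def k(self) -> int:
        return len(self.seed_sets)

    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.seed_sets])

    def nodes(self) -> set:
        return set().union(*[set(s) for s in self.seed_sets]) if self.seed_sets else set()

    def pinned_behaviors(self, v) -> set:
        return {i for i, s in enumerate(self.seed_sets) if v in s}

    @classmethod
    def empty(cls, k: int, variant: str = "S-T") -> "SeedAssignment":
        return cls([[] for _ in range(k)], {}, variant)


def _check_variant(variant: str):
    if variant not in VARIANTS:
        raise InvalidParameterError(f"variant must be one of {VARIANTS}, got {variant!r}")
    single, top = variant.split("-")
    return single == "S", top == "T"


def distribute_behaviors(strategy: str, b: int, behaviors: BehaviorSet) -> np.ndarray:
    """Split a total seed budget ``b`` over behaviors.

    ``lowest_only`` / ``highest_only`` put everything on the cheapest /
    costliest behavior; ``uniform``, ``proportional_cost`` and
    ``inverse_cost`` use largest-remainder apportionment on equal, cost and
    reciprocal-cost weights respectively.
    """
    if b < 1:
        raise InvalidParameterError(f"seed budget must be >= 1, got {b}")
    k = behaviors.k
    out = np.zeros(k, dtype=int)
    if strategy == "lowest_only":
        out[0] = b
        return out
    if strategy == "highest_only":
        out[-1] = b
        return out
    if strategy == "uniform":
        weights = np.ones(k)
    elif strategy == "proportional_cost":
        weights = behaviors.costs.astype(float)
    elif strategy == "inverse_cost":
        weights = 1.0 / behaviors.costs
    else:
        raise InvalidParameterError(f"unknown distribution strategy {strategy!r}")
    quota = b * weights / weights.sum()
    out = np.floor(quota).astype(int)
    remainder = quota - out
    spare = b - out.sum()
    for j in np.argsort(-remainder, kind="stable")[:spare]:
        out[j] += 1
    return out


class _Builder:
    """Accumulates assignments, enforcing affordability / top-up semantics."""

    def __init__(self, ga: GraphArrays, behaviors: BehaviorSet,
                 endow: Endowments, variant: str):
        self.ga = ga
        self.behaviors = behaviors
        self.single, self.top_up = _check_variant(variant)
        self.variant = variant
        n, k = ga.n, behaviors.k
        self.seed_idx = [[] for _ in range(k)]
        self.topped = {}
        self.r = endow.resource.copy()
        self.pinned_cost = np.zeros(n)
        # avail[v, i]: v may still be claimed as a seed for behavior i
        self.avail = np.ones((n, k), dtype=bool)

    def can_afford(self, vi: int, j: int) -> bool:
        need = self.pinned_cost[vi] + self.behaviors.costs[j]
        return need <= self.r[vi] + COST_TOL

    def assign(self, vi: int, j: int) -> bool:
        """Pin behavior j at node vi; returns False if unaffordable in NT."""
        need = self.pinned_cost[vi] + self.behaviors.costs[j]
        if need > self.r[vi] + COST_TOL:
            if not self.top_up:
                return False
            node = self.ga.order[vi]
            self.topped[node] = self.topped.get(node, 0.0) + (need - self.r[vi])
            self.r[vi] = need
        self.pinned_cost[vi] = need
        self.seed_idx[j].append(vi)
        if self.single:
            self.avail[vi, :] = False
        else:
            self.avail[vi, j] = False
        return True

    def build(self) -> SeedAssignment:
        sets = [[self.ga.order[vi] for vi in s] for s in self.seed_idx]
        return SeedAssignment(sets, dict(self.topped), self.variant)


def _infeasible(b: np.ndarray):
    unfilled = [int(i) for i in np.nonzero(b > 0)[0]]
    raise InfeasibleSeedingError(
        f"population exhausted with unfilled seed budget for behaviors {unfilled}"
    )


def _top_by_score(score: np.ndarray, mask: np.ndarray, m: int, rng) -> np.ndarray:
    """Indices of the m highest-scoring nodes among mask, random tie-break."""
    idx = np.nonzero(mask)[0]
    if len(idx) < m:
        return None
    order = np.lexsort((rng.random(len(idx)), -score[idx]))
    return idx[order[:m]]


def _argmax_tiebreak(score: np.ndarray, mask: np.ndarray, rng) -> int:
    idx = np.nonzero(mask)[0]
    vals = score[idx]
    best = vals.max()
    ties = idx[vals == best]
    return int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])


def select_random(G, endow: Endowments, behaviors: BehaviorSet, budget,
                  variant: str = "S-T", rng_seed=None) -> SeedAssignment:
    """Uniformly random seeds (the baseline row of the comparison tables)."""
    ga = G if isinstance(G, GraphArrays) else GraphArrays.from_graph(G)
    rng = np.random.default_rng(rng_seed)
    b = np.asarray(budget, dtype=int).copy()
    bld = _Builder(ga, behaviors, endow, variant)
    if bld.single and b.sum() > ga.n:
        raise InfeasibleSeedingError(f"budget {b.sum()} exceeds population {ga.n}")
    while b.sum() > 0:
        progressed = False
        for vi in rng.permutation(ga.n):
            if b.sum() == 0:
                break
            needed = np.nonzero(b > 0)[0]
            usable = [j for j in needed if bld.avail[vi, j]]
            if not usable:
                continue
            j = int(usable[rng.integers(len(usable))])
            if bld.assign(vi, j):
                b[j] -= 1
                progressed = True
        if not progressed:
            break
    if b.sum() > 0:
        _infeasible(b)
    return bld.build()


def select_naive_degree(G, endow: Endowments, behaviors: BehaviorSet, budget,
                        tie_rule: str = "random_nt", rng_seed=None) -> SeedAssignment:
    """Scan nodes in decreasing degree order and hand out behaviors.

    ``random_nt``: a uniformly random still-needed behavior is assigned only
    if the node can afford it (the node is consumed from the ranking either
    way); ``random_t``: the behavior is assigned regardless and the resource
    topped up; ``knapsack``: the node is pinned with its utility-maximizing
    affordable subset of still-needed behaviors.
    """
    ga = G if isinstance(G, GraphArrays) else GraphArrays.from_graph(G)
    rng = np.random.default_rng(rng_seed)
    b = np.asarray(budget, dtype=int).copy()
    variant = {"random_nt": "S-NT", "random_t": "S-T", "knapsack": "M-NT"}.get(tie_rule)
    if variant is None:
        raise InvalidParameterError(f"unknown tie_rule {tie_rule!r}")
    bld = _Builder(ga, behaviors, endow, variant)
    order = np.lexsort((rng.random(ga.n), -ga.degree.astype(float)))
    for vi in order:
        if b.sum() == 0:
            break
        needed = np.nonzero(b > 0)[0]
        if tie_rule == "knapsack":
            candmask = 0
            for j in needed:
                candmask |= 1 << int(j)
            chosen = _engine.best_subsets(
                behaviors.utilities[None, :].astype(float),
                np.array([candmask]), np.array([endow.resource[vi]]),
                behaviors.costs)[0]
            for j in np.nonzero(chosen)[0]:
                if bld.assign(int(vi), int(j)):
                    b[int(j)] -= 1
        else:
            j = int(needed[rng.integers(len(needed))])
            if bld.assign(int(vi), j):
                b[j] -= 1
    if b.sum() > 0:
        _infeasible(b)
    return bld.build()


def _ranked_rounds(ga, endow, behaviors, budget, scores, rng, variant) -> SeedAssignment:
    """Shared skeleton of the ranked heuristics.

    Each round takes the top-b[i] still-available nodes per behavior,
    resolves multi-behavior claims by a uniformly random pick, tops up (T
    variants), then refills behaviors left short from the next-ranked nodes.
    """
    b = np.asarray(budget, dtype=int).copy()
    bld = _Builder(ga, behaviors, endow, variant)
    while b.sum() > 0:
        claims = {}
        for i in np.nonzero(b > 0)[0]:
            mask = bld.avail[:, i].copy()
            if not bld.top_up:
                mask &= bld.pinned_cost + behaviors.costs[i] <= bld.r + COST_TOL
            top = _top_by_score(scores[i], mask, int(b[i]), rng)
            if top is None:
                _infeasible(b)
            claims[int(i)] = set(int(v) for v in top)
        T = sorted(set().union(*claims.values()))
        for vi in T:
            mine = [i for i, s in claims.items() if vi in s and b[i] > 0]
            if not mine:
                continue
            if bld.single:
                j = int(mine[rng.integers(len(mine))])
                if bld.assign(vi, j):
                    b[j] -= 1
                else:
                    bld.avail[vi, :] = False  # NT: cannot serve, drop from pool
            else:
                for j in mine:
                    if bld.assign(vi, j):
                        b[j] -= 1
                    else:
                        bld.avail[vi, j] = False
    return bld.build()


def select_degree_resource_ranked(G, endow: Endowments, behaviors: BehaviorSet,
                                  budget, rng_seed=None,
                                  variant: str = "S-T") -> SeedAssignment:
    """Rank nodes per behavior by d_i(v), the count of resource-sufficient neighbors."""
    ga = G if isinstance(G, GraphArrays) else GraphArrays.from_graph(G)
    rng = np.random.default_rng(rng_seed)
    afford = (endow.resource[:, None] >= behaviors.costs[None, :] - COST_TOL).astype(float)
    d = (ga.adjacency @ afford).T  # (k, n)
    return _ranked_rounds(ga, endow, behaviors, budget, d, rng, variant)


def ciw(G, endow: Endowments, behaviors: BehaviorSet, i: int,
        excluded=()) -> np.ndarray:
    """Constrained Social Influence Weight e_i(v) for every node.

    ``e_i(v) = 1 + sum 1/|N(u)|`` over neighbors ``u`` outside ``excluded``
    with ``r(u) >= c_i``; a cheap proxy for the one-hop influence of ``v``
    restricted to neighbors able to afford behavior ``i``.
    """
    ga = G if isinstance(G, GraphArrays) else GraphArrays.from_graph(G)
    contrib = _ciw_contrib(ga, endow, behaviors, i)
    if len(excluded):
        contrib = contrib.copy()
        for u in excluded:
            contrib[ga.index.get(u, u)] = 0.0
    return 1.0 + ga.adjacency @ contrib


def _ciw_contrib(ga, endow, behaviors, i):
    ok = endow.resource >= behaviors.costs[i] - COST_TOL
    with np.errstate(divide="ignore"):
        inv = np.where(ga.degree > 0, 1.0 / np.maximum(ga.degree, 1), 0.0)
    return np.where(ok, inv, 0.0)


def select_ciw_ranked(G, endow: Endowments, behaviors: BehaviorSet, budget,
                      rng_seed=None, variant: str = "S-T") -> SeedAssignment:
    """Static ranking on the CIW score, with the shared refill skeleton."""
    ga = G if isinstance(G, GraphArrays) else GraphArrays.from_graph(G)
    rng = np.random.default_rng(rng_seed)
    scores = np.stack([ciw(ga, endow, behaviors, i) for i in range(behaviors.k)])
    return _ranked_rounds(ga, endow, behaviors, budget, scores, rng, variant)


def select_ciw_max_margin(G, endow: Endowments, behaviors: BehaviorSet, budget,
                          rng_seed=None, variant: str = "S-T") -> SeedAssignment:
    """Greedy hill climb on the CIW score.

    Per behavior, repeatedly take the highest-scoring remaining node and
    discount its influence contribution from its neighbors' scores, so later
    picks cover different parts of the network; cross-behavior collisions
    are resolved like the ranked heuristics.
    """
    ga = G if isinstance(G, GraphArrays) else GraphArrays.from_graph(G)
    rng = np.random.default_rng(rng_seed)
    b = np.asarray(budget, dtype=int).copy()
    bld = _Builder(ga, behaviors, endow, variant)

    def hill_climb(i: int, m: int) -> list:
        seeds_i = bld.seed_idx[i]
        contrib = _ciw_contrib(ga, endow, behaviors, i).copy()
        contrib[seeds_i] = 0.0  # current seeds no longer count toward e_i
        e = 1.0 + ga.adjacency @ contrib
        pool = bld.avail[:, i].copy()
        if not bld.top_up:
            pool &= bld.pinned_cost + behaviors.costs[i] <= bld.r + COST_TOL
        picks = []
        for _ in range(m):
            if not pool.any():
                return None
            u = _argmax_tiebreak(e, pool, rng)
            picks.append(u)
            pool[u] = False
            nbrs = ga.neighbors(u)
            live = nbrs[pool[nbrs]]
            e[live] -= contrib[u]
        return picks

    while b.sum() > 0:
        claims = {}
        for i in np.nonzero(b > 0)[0]:
            picks = hill_climb(int(i), int(b[i]))
            if picks is None:
                _infeasible(b)
            claims[int(i)] = set(picks)
        T = sorted(set().union(*claims.values()))
        for vi in T:
            mine = [i for i, s in claims.items() if vi in s and b[i] > 0]
            if not mine:
                continue
            if bld.single:
                j = int(mine[rng.integers(len(mine))])
                if bld.assign(vi, j):
                    b[j] -= 1
                else:
                    bld.avail[vi, :] = False
            else:
                for j in mine:
                    if bld.assign(vi, j):
                        b[j] -= 1
                    else:
                        bld.avail[vi, j] = False
    return bld.build()


def _seed_signals(ga, behaviors, seed_idx) -> np.ndarray:
    """Social signals (n, k) produced by the current seed assignment."""
    n, k = ga.n, behaviors.k
    A = np.zeros((n, k), dtype=bool)
    for i, nodes in enumerate(seed_idx):
        A[list(nodes), i] = True
    return _engine.propagate(ga.weights, A)


def compute_ia(G, endow: Endowments, behaviors: BehaviorSet, seeds,
               i: int, w: float = 0.5) -> float:
    """Expected Immediate Adoption IA_i(S): exact expected count of non-seed
    nodes adopting behavior ``i`` one step after the seeds activate.

    With U(0,1) thresholds, behavior ``j`` is a knapsack candidate at ``v``
    independently with probability ``l_j(v) * 1[c_j <= r(v)]``; the adoption
    probability is computed exactly by enumerating all 2^k candidate sets.
    """
    ga = G if isinstance(G, GraphArrays) else GraphArrays.from_graph(G)
    seed_idx = [[ga.index[v] for v in s] for s in seeds.seed_sets]
    l = _seed_signals(ga, behaviors, seed_idx)
    seed_nodes = sorted(set().union(*[set(s) for s in seed_idx])) if seed_idx else []
    nonseed = np.ones(ga.n, dtype=bool)
    nonseed[seed_nodes] = False
    P = _engine.adoption_probabilities(
        l[nonseed], endow.resource[nonseed], behaviors.costs,
        behaviors.utilities, w)
    return float(P[:, i].sum())


def select_eia(G, endow: Endowments, behaviors: BehaviorSet, budget,
               w: float = 0.5, rng_seed=None, variant: str = "S-T") -> SeedAssignment:
    """Incremental Expected Immediate Adoption heuristic.

    Seeds are committed one at a time: for every behavior still short of
    seeds the candidate with the largest marginal EIA gain is found, and the
    globally best (behavior, node) pair is added.  Gains are computed
    exactly and locally — adding a seed only perturbs the signals of its
    neighbors.
    """
    ga = G if isinstance(G, GraphArrays) else GraphArrays.from_graph(G)
    rng = np.random.default_rng(rng_seed)
    b = np.asarray(budget, dtype=int).copy()
    bld = _Builder(ga, behaviors, endow, variant)
    n, k = ga.n, behaviors.k
    c, u = behaviors.costs, behaviors.utilities
    l = np.zeros((n, k))
    seed_node = np.zeros(n, dtype=bool)
    src, dst = ga.edge_src, ga.edge_dst
    with np.errstate(divide="ignore"):
        inc_dst = np.where(ga.degree[dst] > 0, 1.0 / np.maximum(ga.degree[dst], 1), 0.0)

    while b.sum() > 0:
        P_base = _engine.adoption_probabilities(l, endow.resource, c, u, w)
        best = {}
        for i in np.nonzero(b > 0)[0]:
            i = int(i)
            pool = bld.avail[:, i] & ~seed_node
            if not bld.top_up:
                pool &= bld.pinned_cost + c[i] <= bld.r + COST_TOL
            if not pool.any():
                _infeasible(b)
            l_bump = l[dst].copy()
            l_bump[:, i] = np.minimum(l_bump[:, i] + inc_dst, 1.0)
            P_bump = _engine.adoption_probabilities(
                l_bump, endow.resource[dst], c, u, w)[:, i]
            delta = (P_bump - P_base[dst, i]) * (~seed_node[dst])
            gain = np.zeros(n)
            np.add.at(gain, src, delta)
            gain -= P_base[:, i] * (~seed_node)  # the new seed stops counting
            v = _argmax_tiebreak(gain, pool, rng)
            best[i] = (v, gain[v])
        s_vals = {i: g for i, (_, g) in best.items()}
        top = max(s_vals.values())
        ties = [i for i, g in s_vals.items() if g == top]
        i_max = int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])
        v = best[i_max][0]
        assert bld.assign(v, i_max)
        b[i_max] -= 1
        if bld.single:
            seed_node[v] = True
        nbrs = ga.neighbors(v)
        with np.errstate(divide="ignore"):
            l[nbrs, i_max] = np.minimum(
                l[nbrs, i_max] + 1.0 / np.maximum(ga.degree[nbrs], 1), 1.0)
    return bld.build()


def select_greedy_kkt(G, endow: Endowments, behaviors: BehaviorSet, budget,
                      w: float = 0.5, spread_runs: int = 1000, rng_seed=None,
                      variant: str = "S-T", spread_estimator=None,
                      max_epochs: int = 10_000) -> SeedAssignment:
    """Simulation-based greedy maximization of expected total participation.

    Each round runs a core-greedy scan per behavior: every remaining node is
    evaluated as the next seed by estimating the sticky-dynamics total
    participation (``spread_runs`` Monte-Carlo simulations with fresh
    thresholds, shared across the candidates of one scan as common random
    numbers), and the globally best (behavior, node) pair is committed.
    Submodularity of participation gives the (1 - 1/e) guarantee.

    ``spread_estimator`` may override the Monte-Carlo step with any callable
    ``f(seed_mask (n,k) bool, r_eff (n,)) -> float`` (e.g. exact enumeration
    on small instances, used by the test suite).
    """
    ga = G if isinstance(G, GraphArrays) else GraphArrays.from_graph(G)
    rng = np.random.default_rng(rng_seed)
    b = np.asarray(budget, dtype=int).copy()
    bld = _Builder(ga, behaviors, endow, variant)
    n, k = ga.n, behaviors.k
    c, u = behaviors.costs, behaviors.utilities

    def core_greedy(i: int):
        pool = bld.avail[:, i] & (bld.pinned_cost == 0) if bld.single else bld.avail[:, i]
        pool = pool.copy()
        if not bld.top_up:
            pool &= bld.pinned_cost + c[i] <= bld.r + COST_TOL
        cand = np.nonzero(pool)[0]
        if len(cand) == 0:
            _infeasible(b)
        base_mask = np.zeros((n, k), dtype=bool)
        for j, s in enumerate(bld.seed_idx):
            base_mask[s, j] = True
        if spread_estimator is not None:
            sigma = np.empty(len(cand))
            for idx, vi in enumerate(cand):
                m = base_mask.copy()
                m[vi, i] = True
                r_eff = bld.r.copy()
                need = bld.pinned_cost[vi] + c[i]
                if bld.top_up and need > r_eff[vi]:
                    r_eff[vi] = need
                sigma[idx] = spread_estimator(m, r_eff)
        else:
            theta = rng.random((spread_runs, n, k))
            sigma = np.empty(len(cand))
            chunk = max(1, int(4e6 / max(1, spread_runs * n * k)) )
            for lo in range(0, len(cand), chunk):
                sub = cand[lo:lo + chunk]
                C = len(sub)
                A0 = np.broadcast_to(base_mask, (C, 1, n, k)).copy()
                A0[np.arange(C), 0, sub, i] = True
                r_eff = np.broadcast_to(bld.r, (C, n)).copy()
                if bld.top_up:
                    need = bld.pinned_cost[sub] + c[i]
                    r_eff[np.arange(C), sub] = np.maximum(r_eff[np.arange(C), sub], need)
                A, _, _ = _engine.run_sticky(
                    ga, c, u, w, r_eff[:, None, :], theta, A0, max_epochs)
                sigma[lo:lo + C] = A.any(axis=-1).sum(axis=-1).mean(axis=-1)
        top = sigma.max()
        ties = cand[sigma == top]
        v = int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])
        return v, float(top)

    while b.sum() > 0:
        best = {int(i): core_greedy(int(i)) for i in np.nonzero(b > 0)[0]}
        top = max(s for _, s in best.values())
        ties = [i for i, (_, s) in best.items() if s == top]
        i_max = int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])
        v = best[i_max][0]
        assert bld.assign(v, i_max)
        b[i_max] -= 1
    return bld.build()
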