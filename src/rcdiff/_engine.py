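"""Vectorized array kernels behind the diffusion model.

Everything here works on integer node indices aligned with ``list(G.nodes())``.
States are boolean arrays of shape ``(..., n, k)`` so the same kernels serve
single runs, Monte-Carlo batches, and the batched spread estimation used by
the greedy seed-selection algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import scipy.sparse as sp

COST_TOL = 1e-9


@dataclass
class GraphArrays:
    """CSR influence operator and index maps for one graph."""

    order: tuple
    index: dict
    weights: sp.csr_array  # W[v, u] = 1/deg(v) if {v, u} in E
    adjacency: sp.csr_array  # 0/1
    degree: np.ndarray
    edge_src: np.ndarray  # both orientations of every edge
    edge_dst: np.ndarray

    @classmethod
    def from_graph(cls, G: nx.Graph) -> "GraphArrays":
        order = tuple(G.nodes())
        index = {v: i for i, v in enumerate(order)}
        n = len(order)
        A = nx.to_scipy_sparse_array(G, nodelist=list(order), format="csr", dtype=float)
        deg = np.asarray(A.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros(n), where=deg > 0)
        W = sp.csr_array(sp.diags(inv) @ A)
        coo = A.tocoo()
        return cls(order, index, W, sp.csr_array(A), deg.astype(np.int64),
                   coo.row.copy(), coo.col.copy())

    @property
    def n(self) -> int:
        return len(self.order)

    def neighbors(self, i: int) -> np.ndarray:
        a = self.adjacency
        return a.indices[a.indptr[i]:a.indptr[i + 1]]


@lru_cache(maxsize=32)
def subset_table(costs: tuple):
    """Enumeration of all behavior subsets in knapsack tie-break order.

    Subsets are ordered by (total cost ascending, then lexicographically
    smallest index set), so a first-occurrence argmax over payoffs resolves
    ties exactly as specified.
    Returns (masks, bits, cost) with masks[j] the bitmask of column j.
    """
    k = len(costs)
    c = np.asarray(costs, dtype=float)
    masks = np.arange(2**k)
    bits = (masks[:, None] >> np.arange(k)) & 1
    cost = bits @ c
    lex_keys = [tuple(np.nonzero(row)[0]) for row in bits]
    order = sorted(range(2**k), key=lambda j: (cost[j], lex_keys[j]))
    order = np.asarray(order)
    return masks[order], bits[order].astype(bool), cost[order]


def best_subsets(payoff, candmask, budget, costs, forcedmask=None):
    """Per-node payoff-maximizing feasible behavior subset.

    payoff: (..., n, k); candmask: (..., n) int bitmasks of allowed behaviors;
    budget: broadcastable to (..., n); forcedmask: bitmasks that must be
    contained in the result (pinned seed behaviors).  Returns boolean
    (..., n, k) subset indicators.
    """
    masks, bits, cost = subset_table(tuple(np.asarray(costs, dtype=float)))
    pays = payoff @ bits.T.astype(float)  # (..., n, 2^k)
    feas = (masks & ~candmask[..., None]) == 0
    feas &= cost <= np.asarray(budget)[..., None] + COST_TOL
    if forcedmask is not None:
        feas &= (masks & forcedmask[..., None]) == forcedmask[..., None]
    pays = np.where(feas, pays, -np.inf)
    pick = np.argmax(pays, axis=-1)
    chosen = bits[pick]
    # guard: if nothing was feasible (can only happen with an unaffordable
    # forced set, excluded by construction upstream) keep the forced behaviors
    if forcedmask is not None:
        none_ok = ~np.take_along_axis(feas, pick[..., None], axis=-1)[..., 0]
        if np.any(none_ok):
            kk = payoff.shape[-1]
            forced_bits = ((forcedmask[..., None] >> np.arange(kk)) & 1).astype(bool)
            chosen = np.where(none_ok[..., None], forced_bits, chosen)
    return chosen


def to_bitmask(bools):
    """Boolean (..., k) -> integer bitmask (...,)."""
    k = bools.shape[-1]
    return (bools.astype(np.int64) * (1 << np.arange(k))).sum(axis=-1)


def propagate(W: sp.csr_array, adopted) -> np.ndarray:
    """Social signals l_i(v) = sum of 1/|N(v)| over adopters among N(v).

    adopted: boolean (..., n, k); returns float array of the same shape.
    """
    shape = adopted.shape
    n = shape[-2]
    X = np.moveaxis(adopted, -2, 0).reshape(n, -1).astype(float)
    L = W @ X
    return np.moveaxis(L.reshape((n,) + shape[:-2] + (shape[-1],)), 0, -2)


def run_sticky(ga: GraphArrays, costs, utils, w, r, theta, adopted0, max_epochs):
    """Progressive (sticky) diffusion to quiescence.

    r: (..., n) or (n,); theta: (..., n, k); adopted0: (..., n, k) epoch-0
    state (seed behaviors installed).  Returns (adopted, spent, epochs).
    """
    costs = np.asarray(costs, dtype=float)
    theta = np.asarray(theta)
    full = np.broadcast_shapes(adopted0.shape, theta.shape)
    A = np.broadcast_to(adopted0, full).copy()
    s = A @ costs
    r = np.broadcast_to(np.asarray(r, dtype=float), s.shape)
    epochs = 0
    for _ in range(max_epochs):
        L = propagate(ga.weights, A)
        resid = r - s
        cand = (L >= theta) & (costs <= resid[..., None] + COST_TOL) & ~A
        front = np.nonzero(cand.any(axis=-1))
        if len(front[0]) == 0:
            break
        # knapsack only on the frontier rows (nodes with >= 1 candidate)
        pay = w * utils + (1.0 - w) * L[front]
        chosen = best_subsets(pay, to_bitmask(cand[front]), resid[front], costs)
        if not chosen.any():
            break
        A[front] |= chosen
        s[front] += chosen @ costs
        epochs += 1
    return A, s, epochs


def run_reevaluate(ga: GraphArrays, costs, utils, w, r, theta, adopted0,
                   pinnedmask, max_epochs):
    """Non-progressive diffusion: every epoch each node re-solves its knapsack.

    Adopted behaviors stay eligible without re-passing the threshold test;
    pinned (seed-assigned) behaviors are always retained.  Stops at a state
    fixed point, or after max_epochs with converged=False.
    Returns (adopted, spent, epochs, converged).
    """
    costs = np.asarray(costs, dtype=float)
    A = adopted0.copy()
    r = np.broadcast_to(np.asarray(r, dtype=float), A.shape[:-1])
    converged = False
    epochs = 0
    for _ in range(max_epochs):
        L = propagate(ga.weights, A)
        elig = A | ((L >= theta) & (costs <= r[..., None] + COST_TOL))
        pay = w * utils + (1.0 - w) * L
        chosen = best_subsets(pay, to_bitmask(elig), r, costs, forcedmask=pinnedmask)
        epochs += 1
        if np.array_equal(chosen, A):
            converged = True
            epochs -= 1  # the last epoch changed nothing
            break
        A = chosen
    s = A @ costs
    return A, s, epochs, converged


def adoption_probabilities(l, r, costs, utils, w):
    """Exact one-step adoption probabilities under U(0,1) thresholds.

    Given per-node social signals ``l`` (m, k) and resources ``r`` (m,),
    behavior j is a knapsack candidate independently with probability
    ``l_j * 1[c_j <= r]``; the node adopts the payoff-maximizing feasible
    subset of the realized candidate set.  Returns (m, k) with
    P[node adopts behavior i in one step], obtained by enumerating all 2^k
    candidate sets exactly.
    """
    costs = np.asarray(costs, dtype=float)
    k = len(costs)
    l = np.asarray(l, dtype=float)
    r = np.asarray(r, dtype=float)
    m = l.shape[0]
    masks, bits, cost = subset_table(tuple(costs))
    q = np.where(costs <= r[:, None] + COST_TOL, l, 0.0)
    pay = w * utils + (1.0 - w) * l
    pays_sub = pay @ bits.T.astype(float)  # (m, 2^k)
    afford = cost <= r[:, None] + COST_TOL  # (m, 2^k)
    P = np.zeros((m, k))
    for cmask in range(2**k):
        cbits = (cmask >> np.arange(k)) & 1
        pc = np.prod(np.where(cbits.astype(bool), q, 1.0 - q), axis=1)
        if not pc.any():
            continue
        feas = afford & ((masks & ~cmask) == 0)
        pays = np.where(feas, pays_sub, -np.inf)
        win = np.argmax(pays, axis=1)
        P += pc[:, None] * bits[win]
    return P
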