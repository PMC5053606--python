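"""Independent reference implementations used as test oracles.

These deliberately avoid the package's engine code paths: brute-force
subset enumeration for the knapsack, and exact expectation of the single-
behavior sticky process by enumerating every live-edge configuration.
"""

from itertools import chain, combinations, product

import networkx as nx
import numpy as np


def brute_knapsack(candidates, payoffs, costs, budget, tol=1e-9):
    """Reference knapsack: scan all subsets, max payoff, tie-break by
    (lower total cost, lexicographically smallest index tuple)."""
    cand = sorted(candidates)
    best = None
    best_key = None
    for m in range(len(cand) + 1):
        for sub in combinations(cand, m):
            cost = sum(costs[i] for i in sub)
            if cost > budget + tol:
                continue
            pay = sum(payoffs[i] for i in sub)
            key = (-pay, cost, tuple(sub))
            if best_key is None or key < best_key:
                best_key = key
                best = set(sub)
    return best


def exact_participation_k1(G: nx.Graph, affordable, seeds, node_probs=False):
    """Exact expected participation of the single-behavior sticky process.

    Enumerates every live-edge configuration: each affordable non-seed node
    independently picks one incoming neighbor uniformly; a node activates
    iff it is reachable from a seed through picked edges running over
    affordable nodes.  ``affordable``: dict/array node -> bool (r >= c).
    Returns the expectation (and per-node activation probabilities when
    ``node_probs``).
    """
    nodes = list(G.nodes())
    seeds = set(seeds)
    choosers = [v for v in nodes
                if affordable[v] and v not in seeds and G.degree(v) > 0]
    choice_lists = [list(G.neighbors(v)) for v in choosers]
    total_configs = int(np.prod([len(c) for c in choice_lists])) if choosers else 1
    if total_configs > 400_000:
        raise RuntimeError(f"enumeration too large: {total_configs} configs")

    probs = {v: 0.0 for v in nodes}
    weight = 1.0 / total_configs  # uniform neighbor choice => equal weights
    for combo in product(*choice_lists) if choosers else [()]:
        chosen = dict(zip(choosers, combo))
        active = set(s for s in seeds)
        frontier = True
        while frontier:
            frontier = False
            for v, u in chosen.items():
                if v not in active and u in active:
                    active.add(v)
                    frontier = True
        for v in active:
            probs[v] += weight
    expect = sum(probs.values())
    return (expect, probs) if node_probs else expect


def powerset(iterable):
    s = list(iterable)
    return chain.from_iterable(combinations(s, m) for m in range(len(s) + 1))
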