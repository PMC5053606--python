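"""Monte-Carlo estimation of diffusion metrics.

Three metrics summarize a run: *total participation* (nodes with at least
one behavior), *total adoption* (behavior adoptions summed over nodes) and
*resource utilization* (spent over available resource).  Expectations are
estimated by independent runs under one of two averaging regimes:

* ``threshold_avg`` — one fixed topology; endowments (resources and
  thresholds) are resampled every run and the seed strategy re-applied;
* ``network_avg`` — endowments fixed once; a fresh topology is generated
  every run (requires a generator, not a fixed graph).

The two regimes estimate the same quantities for the random-graph ensembles
used here, which the test suite checks empirically.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import _engine
from ._engine import GraphArrays
from .errors import ConfigurationError, UndefinedMetricError
from .model_core import BehaviorSet, DiffusionState, Endowments, run_diffusion, sample_endowments

__all__ = ["MetricEstimate", "resource_utilization", "estimate", "max_possible_utilization"]


@dataclass
class MetricEstimate:
    """Means and standard errors of the three diffusion metrics."""

    participation_mean: float
    participation_se: float
    adoption_mean: float
    adoption_se: float
    utilization_mean: float
    utilization_se: float
    runs: int
    regime: str
    participation: np.ndarray = None  # per-run samples
    adoption: np.ndarray = None
    utilization: np.ndarray = None

    @classmethod
    def from_samples(cls, part, adopt, util, regime):
        part = np.asarray(part, dtype=float)
        adopt = np.asarray(adopt, dtype=float)
        util = np.asarray(util, dtype=float)
        runs = len(part)

        def se(x):
            return float(x.std(ddof=1) / np.sqrt(runs)) if runs > 1 else 0.0

        return cls(float(part.mean()), se(part), float(adopt.mean()), se(adopt),
                   float(util.mean()), se(util), runs, regime, part, adopt, util)


def resource_utilization(state: DiffusionState, endow: Endowments) -> float:
    """Ratio of spent to available resource, post top-up."""
    total = float(endow.resource.sum())
    if total <= 0:
        raise UndefinedMetricError("total network resource is zero")
    return float(state.spent.sum() / total)


def _resolve_topology(graph_or_generator, regime, rng):
    if callable(graph_or_generator):
        return graph_or_generator(rng), True
    if regime == "network_avg":
        raise ConfigurationError(
            "network_avg needs a topology generator, not a fixed graph")
    return graph_or_generator, False


def estimate(graph_or_generator, behaviors: BehaviorSet, seed_strategy,
             w: float = 0.5, mode: str = "reevaluate", runs: int = 5000,
             regime: str = "threshold_avg", rng_seed=None,
             max_epochs: int = 1000,
             reselect: str = "each_run") -> MetricEstimate:
    """Monte-Carlo metric estimate over ``runs`` independent diffusions.

    ``graph_or_generator`` is a graph or a callable ``gen(rng) -> Graph``;
    ``seed_strategy`` is ``None`` (no seeds) or a callable
    ``(G, endow, rng) -> SeedAssignment``.  ``reselect`` (threshold average
    only) controls how the seed selection interacts with the per-run
    endowment resampling:

    * ``"each_run"`` — endowments resampled and the strategy re-applied
      every run (the default; selection sees each run's resources);
    * ``"seeds_frozen"`` — the strategy runs once on a selection draw; each
      run still resamples the endowments, re-deriving the seeds' top-ups so
      they can afford their pinned behaviors.  The cheap evaluation mode
      for expensive selection algorithms (e.g. the simulation greedy);
    * ``"thresholds_only"`` — endowments drawn once, seeds selected once,
      only thresholds resampled.
    """
    if regime not in ("threshold_avg", "network_avg"):
        raise ConfigurationError(f"unknown regime {regime!r}")
    if reselect not in ("each_run", "seeds_frozen", "thresholds_only"):
        raise ConfigurationError(f"unknown reselect policy {reselect!r}")
    if runs < 1:
        raise ConfigurationError("runs must be >= 1")
    rng = np.random.default_rng(rng_seed)
    k = behaviors.k

    fixed_graph = None
    fixed_endow = None
    fixed_seeds = None
    if regime == "threshold_avg":
        fixed_graph, _ = _resolve_topology(graph_or_generator, regime, rng)
        fixed_graph = GraphArrays.from_graph(fixed_graph) \
            if not isinstance(fixed_graph, GraphArrays) else fixed_graph
        if reselect != "each_run":
            fixed_endow = _sample_endow_arrays(fixed_graph.n, k, rng)
            fixed_seeds = seed_strategy(fixed_graph, fixed_endow, rng) \
                if seed_strategy is not None else None
    else:
        if not callable(graph_or_generator):
            raise ConfigurationError(
                "network_avg needs a topology generator, not a fixed graph")
        probe = graph_or_generator(rng)
        fixed_endow = _sample_endow_arrays(probe.number_of_nodes(), k, rng)

    part = np.empty(runs)
    adopt = np.empty(runs)
    util = np.empty(runs)
    for j in range(runs):
        if regime == "threshold_avg":
            ga = fixed_graph
            if reselect == "each_run":
                endow = _sample_endow_arrays(ga.n, k, rng)
                seeds = seed_strategy(ga, endow, rng) if seed_strategy else None
            elif reselect == "seeds_frozen":
                endow = _sample_endow_arrays(ga.n, k, rng)
                seeds = _retarget_top_ups(fixed_seeds, behaviors, endow, ga)
            else:
                endow = Endowments(fixed_endow.resource,
                                   rng.random((ga.n, k)))
                seeds = fixed_seeds
        else:
            G = graph_or_generator(rng)
            ga = GraphArrays.from_graph(G)
            endow = fixed_endow
            seeds = seed_strategy(ga, endow, rng) if seed_strategy else None
        res, _ = run_diffusion(ga, endow, behaviors, seeds, w=w, mode=mode,
                               max_epochs=max_epochs)
        part[j] = res.participation
        adopt[j] = res.adoption
        util[j] = res.utilization
    return MetricEstimate.from_samples(part, adopt, util, regime)


def _retarget_top_ups(seeds, behaviors, endow, ga):
    """Rebuild a frozen assignment's top-ups for freshly drawn resources."""
    if seeds is None:
        return None
    need = {}
    for i, nodes in enumerate(seeds.seed_sets):
        for v in nodes:
            need[v] = need.get(v, 0.0) + float(behaviors.costs[i])
    topped = {}
    for v, total in need.items():
        short = total - float(endow.resource[ga.index[v]])
        if short > 0:
            topped[v] = short
    return type(seeds)(seeds.seed_sets, topped, seeds.variant)


def _sample_endow_arrays(n, k, rng):
    return Endowments(rng.random(n), rng.random((n, k)))


def max_possible_utilization(graph_or_generator, behaviors: BehaviorSet,
                             w: float = 0.5, runs: int = 5000,
                             regime: str = "threshold_avg", rng_seed=None,
                             max_epochs: int = 1000,
                             diffuse: bool = True) -> MetricEstimate:
    """Utilization upper estimate with every node seeded.

    Epoch 0: each node adopts its intrinsic-utility knapsack optimum
    (signal-free, thresholds bypassed); diffusion then runs in re-evaluation
    mode to equilibrium, during which nodes realign with their neighborhood
    — nothing is pinned.  ``diffuse=False`` reports the epoch-0 metrics,
    whose expectation is the closed-form full-utilization-points bound.
    """
    if regime not in ("threshold_avg", "network_avg"):
        raise ConfigurationError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(rng_seed)
    k = behaviors.k
    c, u = behaviors.costs, behaviors.utilities

    fixed_graph = None
    fixed_endow = None
    if regime == "threshold_avg":
        G, _ = _resolve_topology(graph_or_generator, regime, rng)
        fixed_graph = G if isinstance(G, GraphArrays) else GraphArrays.from_graph(G)
    else:
        if not callable(graph_or_generator):
            raise ConfigurationError(
                "network_avg needs a topology generator, not a fixed graph")
        probe = graph_or_generator(rng)
        fixed_endow = _sample_endow_arrays(probe.number_of_nodes(), k, rng)

    part = np.empty(runs)
    adopt = np.empty(runs)
    util = np.empty(runs)
    full = (1 << k) - 1
    for j in range(runs):
        if regime == "threshold_avg":
            ga = fixed_graph
            endow = _sample_endow_arrays(ga.n, k, rng)
        else:
            ga = GraphArrays.from_graph(graph_or_generator(rng))
            endow = fixed_endow
        r = endow.resource
        A0 = _engine.best_subsets(
            np.broadcast_to(u, (ga.n, k)).astype(float),
            np.full(ga.n, full), r, c)
        if diffuse:
            A, s, _, _ = _engine.run_reevaluate(
                ga, c, u, w, r, endow.thresholds, A0,
                np.zeros(ga.n, dtype=np.int64), max_epochs)
        else:
            A, s = A0, A0 @ c
        total = r.sum()
        part[j] = A.any(axis=1).sum()
        adopt[j] = A.sum()
        util[j] = s.sum() / total if total > 0 else 0.0
    return MetricEstimate.from_samples(part, adopt, util, regime)
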