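"""Configuration-driven experiment grids.

Reproduces, at configurable scale, the standard comparison grids of the
seed-selection study: the all-nodes-seeded utilization ceiling (table 2),
heuristic comparisons on utilization (table 3) and participation/adoption
(table 4), the greedy-vs-heuristics comparison on small instances
(table 5), and the behavior-distribution sweeps (tables 6 and 7).

Default study conditions: three behaviors with costs (0.2, 0.5, 0.7) and
utility equal to cost, payoff weight w = 0.5, re-evaluation dynamics,
synthetic topologies of 500 nodes, seed fraction alpha = 0.1 rounded to a
multiple of the behavior count (b = 51), S-T variant, uniform behavior
distribution unless swept.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import graphs, metrics_mc, seeding
from ._engine import GraphArrays
from .errors import ConfigurationError, InvalidParameterError
from .model_core import BehaviorSet

log = logging.getLogger(__name__)

__all__ = ["seed_budget", "default_behaviors", "make_generator",
           "seed_strategy", "run_table", "HEURISTICS", "TOPOLOGIES",
           "DISTRIBUTIONS"]

TOPOLOGIES = ("pa", "sw", "sc")
DISTRIBUTIONS = ("lowest_only", "inverse_cost", "uniform",
                 "proportional_cost", "highest_only")
HEURISTICS = ("random", "degree_nt", "degree_knap", "degree_t",
              "degree_resource", "ciw_rank", "ciw_margin", "eia", "greedy")


def default_behaviors() -> BehaviorSet:
    """Three test behaviors, costs (0.2, 0.5, 0.7), utility proportional to cost."""
    return BehaviorSet.proportional([0.2, 0.5, 0.7])


def seed_budget(alpha: float, n: int, k: int = 3) -> int:
    """Total seed budget: round(alpha * n), adjusted up to a multiple of k."""
    if not 0 < alpha <= 1:
        raise ConfigurationError(f"alpha must lie in (0, 1], got {alpha}")
    b0 = round(alpha * n)
    b = ((b0 + k - 1) // k) * k
    if b < 1:
        raise ConfigurationError(f"alpha={alpha} yields an empty seed budget for n={n}")
    return int(b)


def make_generator(model: str, n: int, **params):
    """A callable ``gen(rng) -> Graph`` for one synthetic topology model."""
    def gen(rng):
        seed = int(np.random.default_rng(rng).integers(2**31 - 1))
        if model == "pa":
            return graphs.gen_preferential_attachment(n, seed)
        if model == "sw":
            return graphs.gen_small_world(n, params.get("lattice_k", 2),
                                          params.get("p_rewire", 0.2), seed)
        if model == "sc":
            return graphs.gen_spatially_clustered(n, params.get("avg_degree", 10.0), seed)
        raise InvalidParameterError(f"unknown topology model {model!r}")
    gen.model = model
    gen.n = n
    return gen


def seed_strategy(heuristic: str, budget, w: float = 0.5,
                  variant: str = "S-T", spread_runs: int = 200):
    """A per-run selection callable ``(G, endow, rng) -> SeedAssignment``."""
    budget = np.asarray(budget, dtype=int)

    def strat(G, endow, rng):
        child = int(np.random.default_rng(rng).integers(2**31 - 1))
        behaviors = strat.behaviors
        if heuristic == "random":
            return seeding.select_random(G, endow, behaviors, budget, variant, child)
        if heuristic == "degree_nt":
            return seeding.select_naive_degree(G, endow, behaviors, budget, "random_nt", child)
        if heuristic == "degree_t":
            return seeding.select_naive_degree(G, endow, behaviors, budget, "random_t", child)
        if heuristic == "degree_knap":
            return seeding.select_naive_degree(G, endow, behaviors, budget, "knapsack", child)
        if heuristic == "degree_resource":
            return seeding.select_degree_resource_ranked(G, endow, behaviors, budget,
                                                         child, variant)
        if heuristic == "ciw_rank":
            return seeding.select_ciw_ranked(G, endow, behaviors, budget, child, variant)
        if heuristic == "ciw_margin":
            return seeding.select_ciw_max_margin(G, endow, behaviors, budget, child, variant)
        if heuristic == "eia":
            return seeding.select_eia(G, endow, behaviors, budget, w, child, variant)
        if heuristic == "greedy":
            return seeding.select_greedy_kkt(G, endow, behaviors, budget, w,
                                             spread_runs, child, variant)
        raise InvalidParameterError(f"unknown heuristic {heuristic!r}")

    strat.behaviors = default_behaviors()
    strat.heuristic = heuristic
    return strat


def _topologies_for(table_id, n, graph_path):
    items = [(name, make_generator(name, n)) for name in TOPOLOGIES]
    if graph_path is not None:
        G = graphs.read_edge_list(graph_path)
        items.append(("qc", G))
    elif table_id != 5:
        log.info("no external graph supplied; real-network column skipped")
    return items


def _row(base, est, n):
    return dict(
        base,
        participation_mean=est.participation_mean,
        participation_se=est.participation_se,
        participation_pct=100.0 * est.participation_mean / n,
        adoption_mean=est.adoption_mean,
        adoption_se=est.adoption_se,
        adoption_pct=100.0 * est.adoption_mean / n,
        utilization_mean=est.utilization_mean,
        utilization_se=est.utilization_se,
        runs=est.runs,
    )


def run_table(table_id: int, runs: int = 5000, rng_seed=0, n: int = 500,
              w: float = 0.5, mode: str = "reevaluate", alpha: float = 0.1,
              variant: str = "S-T", spread_runs: int = 200,
              graph_path=None, out_dir=None,
              heuristics=None) -> pd.DataFrame:
    """Run one experiment grid; returns a tidy DataFrame (one row per cell).

    Every row carries the full configuration including the RNG seed, so any
    row can be reproduced in isolation.
    """
    if table_id not in (2, 3, 4, 5, 6, 7):
        raise ConfigurationError(f"unknown table id {table_id}")
    behaviors = default_behaviors()
    k = behaviors.k
    if table_id == 5:
        n = min(n, 100)
    rows = []
    base_common = dict(table=table_id, n=n, w=w, mode=mode, variant=variant,
                       rng_seed=rng_seed)

    if table_id == 2:
        for name, topo in _topologies_for(table_id, n, graph_path):
            for regime in ("threshold_avg", "network_avg"):
                if regime == "network_avg" and not callable(topo):
                    continue
                est = metrics_mc.max_possible_utilization(
                    topo, behaviors, w=w, runs=runs, regime=regime,
                    rng_seed=_cell_seed(rng_seed, name, regime))
                rows.append(_row(dict(base_common, topology=name, regime=regime,
                                      heuristic="all_seeded", distribution="-",
                                      budget=n), est, n))
    elif table_id in (3, 4):
        hs = heuristics or [h for h in HEURISTICS if h != "greedy"]
        for name, topo in _topologies_for(table_id, n, graph_path):
            nn = topo.n if callable(topo) else topo.number_of_nodes()
            b = seed_budget(alpha, nn, k)
            budget = seeding.distribute_behaviors("uniform", b, behaviors)
            for h in hs:
                strat = seed_strategy(h, budget, w=w, variant=variant)
                est = metrics_mc.estimate(
                    topo, behaviors, strat, w=w, mode=mode, runs=runs,
                    regime="threshold_avg",
                    rng_seed=_cell_seed(rng_seed, name, h))
                rows.append(_row(dict(base_common, topology=name,
                                      regime="threshold_avg", heuristic=h,
                                      distribution="uniform", budget=b), est, nn))
    elif table_id == 5:
        b = 9
        budget = seeding.distribute_behaviors("uniform", b, behaviors)
        hs = heuristics or ["greedy", "ciw_rank", "ciw_margin", "eia"]
        for name, topo in _topologies_for(table_id, n, None):
            for h in hs:
                strat = seed_strategy(h, budget, w=w, variant=variant,
                                      spread_runs=spread_runs)
                est = metrics_mc.estimate(
                    topo, behaviors, strat, w=w, mode=mode, runs=runs,
                    regime="threshold_avg",
                    reselect=("each_run" if h != "greedy" else "seeds_frozen"),
                    rng_seed=_cell_seed(rng_seed, name, h))
                rows.append(_row(dict(base_common, topology=name,
                                      regime="threshold_avg", heuristic=h,
                                      distribution="uniform", budget=b), est, n))
    else:  # tables 6 and 7: distribution sweep with the CIW max-margin seeds
        for name, topo in _topologies_for(table_id, n, graph_path):
            nn = topo.n if callable(topo) else topo.number_of_nodes()
            b = seed_budget(alpha, nn, k)
            for dist in DISTRIBUTIONS:
                budget = seeding.distribute_behaviors(dist, b, behaviors)
                strat = seed_strategy("ciw_margin", budget, w=w, variant=variant)
                est = metrics_mc.estimate(
                    topo, behaviors, strat, w=w, mode=mode, runs=runs,
                    regime="threshold_avg",
                    rng_seed=_cell_seed(rng_seed, name, dist))
                rows.append(_row(dict(base_common, topology=name,
                                      regime="threshold_avg",
                                      heuristic="ciw_margin",
                                      distribution=dist, budget=b), est, nn))

    df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"table{table_id}.csv", index=False)
        (out / f"table{table_id}.json").write_text(
            json.dumps(df.to_dict(orient="records"), indent=2, default=float))
    return df


def _cell_seed(rng_seed, *labels) -> int:
    """Stable per-cell child seed so cells rerun identically in isolation."""
    tag = zlib.crc32("/".join(str(x) for x in labels).encode())
    ss = np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, tag & 0x7FFFFFFF])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
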