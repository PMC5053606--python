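import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rcdiff import _engine, seeding
from rcdiff.errors import InfeasibleSeedingError
from rcdiff.experiments import seed_strategy
from rcdiff.model_core import BehaviorSet, Endowments

from _oracles import exact_participation_k1
from conftest import rich_endowments


# ---------------------------------------------------------------- distribution

def test_distribute_behaviors_examples(behaviors3):
    assert list(seeding.distribute_behaviors("uniform", 51, behaviors3)) == [17, 17, 17]
    assert list(seeding.distribute_behaviors("highest_only", 51, behaviors3)) == [0, 0, 51]
    assert list(seeding.distribute_behaviors("lowest_only", 51, behaviors3)) == [51, 0, 0]
    # weights 0.2/1.4*51 = 7.29, 18.21, 25.5 -> largest remainder to behavior 3
    assert list(seeding.distribute_behaviors("proportional_cost", 51, behaviors3)) == [7, 18, 26]


@given(b=st.integers(1, 400), strategy=st.sampled_from(
    ["lowest_only", "inverse_cost", "uniform", "proportional_cost", "highest_only"]))
def test_distribute_behaviors_sums_to_budget(b, strategy):
    bs = BehaviorSet.proportional([0.2, 0.5, 0.7])
    counts = seeding.distribute_behaviors(strategy, b, bs)
    assert counts.sum() == b
    assert np.all(counts >= 0)


# ---------------------------------------------------------------- random

def test_select_random_fill_and_determinism(behaviors3):
    G = nx.path_graph(3)
    endow = rich_endowments(3, 3)
    empty = seeding.select_random(G, endow, behaviors3, [0, 0, 0], "S-T", 1)
    assert empty.counts().sum() == 0
    full = seeding.select_random(G, endow, behaviors3, [1, 1, 1], "S-T", 1)
    assert full.nodes() == {0, 1, 2}
    a1 = seeding.select_random(G, endow, behaviors3, [1, 1, 1], "S-T", 7)
    a2 = seeding.select_random(G, endow, behaviors3, [1, 1, 1], "S-T", 7)
    assert a1.seed_sets == a2.seed_sets
    with pytest.raises(InfeasibleSeedingError):
        seeding.select_random(G, endow, behaviors3, [2, 2, 2], "S-T", 1)


# ---------------------------------------------------------------- naive degree

def _broom():
    """Distinct top degrees: deg(0)=4, deg(1)=3, deg(2)=deg(3)=2, deg(4)=1."""
    G = nx.Graph([(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (1, 3)])
    return G


def test_naive_degree_assigns_top_degrees_one_behavior_each(behaviors3):
    G = _broom()
    endow = rich_endowments(5, 3)
    assn = seeding.select_naive_degree(G, endow, behaviors3, [1, 1, 0],
                                       "random_nt", 3)
    assert assn.nodes() == {0, 1}
    assert assn.counts().tolist() == [1, 1, 0]
    assert all(len(assn.pinned_behaviors(v)) == 1 for v in (0, 1))


def test_naive_degree_no_top_up_consumes_poor_nodes(behaviors3):
    G = nx.star_graph(4)
    endow = rich_endowments(5, 3)
    endow.resource[0] = 0.1  # center cannot afford any behavior
    assn = seeding.select_naive_degree(G, endow, behaviors3, [1, 0, 0],
                                       "random_nt", 0)
    assert 0 not in assn.nodes()  # consumed from the ranking, not assigned
    assert assn.counts().tolist() == [1, 0, 0]
    assert assn.topped_up == {}


def test_naive_degree_top_up_raises_resource(behaviors3):
    G = nx.star_graph(4)
    endow = rich_endowments(5, 3)
    endow.resource[0] = 0.05
    assn = seeding.select_naive_degree(G, endow, behaviors3, [0, 0, 1],
                                       "random_t", 0)
    assert assn.seed_sets[2] == [0]  # highest degree regardless of resource
    assert assn.topped_up[0] == pytest.approx(0.65)


def test_naive_degree_knapsack_assigns_utility_optimal_subset(behaviors3):
    G = nx.star_graph(4)
    endow = rich_endowments(5, 3)
    endow.resource[0] = 0.75  # best utility subset within 0.75 is {0.2, 0.5}
    assn = seeding.select_naive_degree(G, endow, behaviors3, [1, 1, 1],
                                       "knapsack", 0)
    assert assn.pinned_behaviors(0) == {0, 1}
    assert assn.counts().sum() == 3  # remaining behavior filled by a leaf


def test_naive_degree_infeasible_names_behaviors(behaviors3):
    G = nx.path_graph(3)
    endow = Endowments(np.full(3, 0.1), np.zeros((3, 3)))
    with pytest.raises(InfeasibleSeedingError, match=r"\[0"):
        seeding.select_naive_degree(G, endow, behaviors3, [2, 0, 0],
                                    "random_nt", 0)


# ---------------------------------------------------------- degree + resource

def test_degree_resource_scores(behaviors3):
    G = nx.star_graph(5)
    endow = rich_endowments(6, 3)
    assn = seeding.select_degree_resource_ranked(G, endow, behaviors3,
                                                 [1, 0, 0], 0)
    assert assn.seed_sets[0] == [0]  # d_i(center) = 5 dominates
    endow.resource[1:] = 0.1  # all neighbors now resource-poor for every behavior
    ga = _engine.GraphArrays.from_graph(G)
    afford = (endow.resource[:, None] >= behaviors3.costs[None, :] - 1e-9).astype(float)
    d = (ga.adjacency @ afford).T
    assert np.all(d[:, 0] <= 1)  # only the rich center contributes


def test_degree_resource_collision_refills_next_ranked(behaviors3):
    # node 0 tops both rankings; it gets exactly one behavior and the other
    # behavior refills from the next-ranked node
    G = _broom()
    endow = rich_endowments(5, 3)
    assn = seeding.select_degree_resource_ranked(G, endow, behaviors3,
                                                 [1, 1, 0], 11)
    assert len(assn.pinned_behaviors(0)) == 1
    assert assn.counts().tolist() == [1, 1, 0]
    assert len(assn.nodes()) == 2


# ---------------------------------------------------------------- CIW

def test_ciw_values_on_star(behaviors3):
    G = nx.star_graph(5)
    G.add_node(6)  # isolated
    endow = rich_endowments(7, 3)
    e = seeding.ciw(G, endow, behaviors3, 0)
    assert e[0] == pytest.approx(6.0)      # 1 + 5 * (1/1)
    assert e[1] == pytest.approx(1.2)      # 1 + 1/5
    assert e[6] == pytest.approx(1.0)      # isolated: initialization only
    e_excl = seeding.ciw(G, endow, behaviors3, 0, excluded=[1])
    assert e_excl[0] == pytest.approx(5.0)
    # resource-poor neighbors stop contributing
    endow.resource[1:6] = 0.1
    assert seeding.ciw(G, endow, behaviors3, 2)[0] == pytest.approx(1.0)


def test_ciw_ranked_picks_center_and_detects_pigeonhole(behaviors3):
    G = nx.star_graph(5)
    endow = rich_endowments(6, 3)
    assn = seeding.select_ciw_ranked(G, endow, behaviors3, [1, 0, 0], 5)
    assert assn.seed_sets[0] == [0]
    a1 = seeding.select_ciw_ranked(G, endow, behaviors3, [2, 2, 2], 9)
    a2 = seeding.select_ciw_ranked(G, endow, behaviors3, [2, 2, 2], 9)
    assert a1.seed_sets == a2.seed_sets
    with pytest.raises(InfeasibleSeedingError):
        seeding.select_ciw_ranked(G, endow, behaviors3, [6, 6, 6], 1)


def _alg7_reference(G, resource, cost, m):
    """Literal hill-climb trace: recompute e, then m argmax picks, each
    followed by discounting the chosen node's contribution at its
    neighbors.  Fixture must be tie-free."""
    e = {v: 1.0 + sum(1.0 / G.degree(u) for u in G.neighbors(v)
                      if resource[u] >= cost)
         for v in G.nodes()}
    pool = set(G.nodes())
    picks = []
    for _ in range(m):
        u = max(pool, key=lambda v: e[v])
        picks.append(u)
        pool.discard(u)
        for v in G.neighbors(u):
            if v in pool and resource[u] >= cost:
                e[v] -= 1.0 / G.degree(u)
    return picks


def test_ciw_max_margin_matches_reference_trace():
    bs = BehaviorSet([0.3], [0.3])
    G = nx.Graph([(0, 1), (0, 2), (0, 3), (1, 4), (4, 5), (2, 3)])
    rng = np.random.default_rng(13)
    resource = 0.35 + 0.6 * rng.random(6)
    endow = Endowments(resource, np.zeros((6, 1)))
    ref = _alg7_reference(G, resource, 0.3, 2)
    assn = seeding.select_ciw_max_margin(G, endow, bs, [2], 5)
    assert sorted(assn.seed_sets[0]) == sorted(ref)


def test_ciw_max_margin_first_pick_matches_ranked(behaviors3):
    G = _broom()
    endow = rich_endowments(5, 3)
    ranked = seeding.select_ciw_ranked(G, endow, behaviors3, [1, 0, 0], 2)
    margin = seeding.select_ciw_max_margin(G, endow, behaviors3, [1, 0, 0], 2)
    assert ranked.seed_sets[0] == margin.seed_sets[0]


def test_ciw_max_margin_discounts_adjacent_hub():
    """After picking hub A, its neighbor hub B loses A's contribution."""
    bs = BehaviorSet([0.3], [0.3])
    # two adjacent hubs with leaf fans; A slightly larger
    G = nx.Graph([("A", "B")])
    G.add_edges_from([("A", f"a{i}") for i in range(4)])
    G.add_edges_from([("B", f"b{i}") for i in range(3)])
    endow = rich_endowments(G.number_of_nodes(), 1)
    assn = seeding.select_ciw_max_margin(G, endow, bs, [2], 0)
    # B's discounted score 1 + 3 - 1/deg(A) = 3.8 still beats any leaf
    assert set(assn.seed_sets[0]) == {"A", "B"}


# ---------------------------------------------------------------- EIA

def _single_assignment(node, k, cost, resource):
    return seeding.SeedAssignment(
        [[node]] + [[] for _ in range(k - 1)],
        {node: max(0.0, cost - resource[node])}, "S-T")


def test_compute_ia_closed_forms():
    bs = BehaviorSet([0.2], [0.2])
    # degree-1 node whose only neighbor is the seed: adopts w.p. 1
    G = nx.path_graph(2)
    endow = rich_endowments(2, 1)
    assn = _single_assignment(0, 1, 0.2, endow.resource)
    assert seeding.compute_ia(G, endow, bs, assn, 0) == pytest.approx(1.0)
    # no node adjacent to a seed of behavior 0
    far = seeding.SeedAssignment([[]], {}, "S-T")
    assert seeding.compute_ia(G, endow, bs, far, 0) == 0.0
    # degree-2 node with one seeded neighbor: candidate w.p. 1/2
    G3 = nx.path_graph(3)
    endow3 = rich_endowments(3, 1)
    assn3 = _single_assignment(0, 1, 0.2, endow3.resource)
    assert seeding.compute_ia(G3, endow3, bs, assn3, 0) == pytest.approx(0.5)


def test_compute_ia_matches_one_step_monte_carlo(behaviors3):
    """Exact 2^k enumeration equals a one-step simulation within 3 SE."""
    G = nx.gnp_random_graph(12, 0.3, seed=5)
    rng = np.random.default_rng(6)
    endow = Endowments(rng.random(12), np.zeros((12, 3)))
    seeds = seeding.SeedAssignment(
        [[0], [1], [2]],
        {v: max(0.0, c - endow.resource[v])
         for v, c in zip((0, 1, 2), behaviors3.costs)}, "S-T")
    ia = [seeding.compute_ia(G, endow, behaviors3, seeds, i) for i in range(3)]

    ga = _engine.GraphArrays.from_graph(G)
    R = 30_000
    theta = np.random.default_rng(7).random((R, 12, 3))
    A0 = np.zeros((R, 12, 3), dtype=bool)
    for i, nodes in enumerate(seeds.seed_sets):
        A0[:, nodes, i] = True
    r_eff = endow.resource.copy()
    for v, extra in seeds.topped_up.items():
        r_eff[v] += extra
    A, _, _ = _engine.run_sticky(ga, behaviors3.costs, behaviors3.utilities,
                                 0.5, r_eff, theta, A0, max_epochs=1)
    new = A & ~A0
    nonseed = np.ones(12, dtype=bool)
    nonseed[[0, 1, 2]] = False
    counts = new[:, nonseed, :].sum(axis=1)  # (R, k)
    for i in range(3):
        se = max(counts[:, i].std(ddof=1) / np.sqrt(R), 1e-12)
        assert abs(counts[:, i].mean() - ia[i]) <= 3 * se


def test_select_eia_brute_force_single_seed():
    bs = BehaviorSet([0.3], [0.3])
    G = nx.gnp_random_graph(15, 0.25, seed=9)
    rng = np.random.default_rng(10)
    endow = Endowments(rng.random(15), np.zeros((15, 1)))
    best = max(
        seeding.compute_ia(G, endow, bs,
                           _single_assignment(v, 1, 0.3, endow.resource), 0)
        for v in G.nodes())
    assn = seeding.select_eia(G, endow, bs, [1], rng_seed=3)
    got = seeding.compute_ia(
        G, endow, bs,
        _single_assignment(assn.seed_sets[0][0], 1, 0.3, endow.resource), 0)
    assert got == pytest.approx(best)


def test_select_eia_empty_budget_and_no_repeats(behaviors3):
    G = nx.gnp_random_graph(10, 0.4, seed=2)
    endow = rich_endowments(10, 3)
    empty = seeding.select_eia(G, endow, behaviors3, [0, 0, 0], rng_seed=1)
    assert empty.counts().sum() == 0
    assn = seeding.select_eia(G, endow, behaviors3, [2, 2, 2], rng_seed=1)
    assert len(assn.nodes()) == 6  # committed nodes never selected twice


# ---------------------------------------------------------------- greedy

def _exact_sigma_estimator(G, cost):
    def estimator(mask, r_eff):
        seeds = {v for v in G.nodes() if mask[v, 0]}
        afford = {v: (r_eff[v] >= cost - 1e-9) or v in seeds for v in G.nodes()}
        return exact_participation_k1(G, afford, seeds)
    return estimator


def test_greedy_single_seed_matches_brute_force():
    bs = BehaviorSet([0.4], [0.4])
    G = nx.gnp_random_graph(8, 0.3, seed=14)
    rng = np.random.default_rng(15)
    endow = Endowments(rng.random(8), np.zeros((8, 1)))
    est = _exact_sigma_estimator(G, 0.4)

    def sigma_of(v):
        mask = np.zeros((8, 1), dtype=bool)
        mask[v, 0] = True
        r_eff = endow.resource.copy()
        r_eff[v] = max(r_eff[v], 0.4)
        return est(mask, r_eff)

    best = max(sigma_of(v) for v in G.nodes())
    assn = seeding.select_greedy_kkt(G, endow, bs, [1], spread_estimator=est,
                                     rng_seed=5)
    assert sigma_of(assn.seed_sets[0][0]) == pytest.approx(best)


def test_greedy_achieves_1_minus_1_over_e_of_optimum():
    """Submodular guarantee against brute-force OPT on enumerable instances."""
    bs = BehaviorSet([0.4], [0.4])
    for gseed in (3, 4, 5):
        G = nx.gnp_random_graph(7, 0.35, seed=gseed)
        rng = np.random.default_rng(gseed)
        endow = Endowments(rng.random(7), np.zeros((7, 1)))
        est = _exact_sigma_estimator(G, 0.4)

        def sigma_of(nodes):
            mask = np.zeros((7, 1), dtype=bool)
            r_eff = endow.resource.copy()
            for v in nodes:
                mask[v, 0] = True
                r_eff[v] = max(r_eff[v], 0.4)
            return est(mask, r_eff)

        opt = max(sigma_of(pair) for pair in itertools.combinations(G.nodes(), 2))
        assn = seeding.select_greedy_kkt(G, endow, bs, [2],
                                         spread_estimator=est, rng_seed=6)
        achieved = sigma_of(assn.seed_sets[0])
        assert achieved >= (1 - 1 / np.e) * opt - 1e-9


def test_greedy_monte_carlo_deterministic(behaviors3):
    G = nx.gnp_random_graph(20, 0.2, seed=30)
    endow = rich_endowments(20, 3, resource=0.8)
    a1 = seeding.select_greedy_kkt(G, endow, behaviors3, [1, 1, 0],
                                   spread_runs=50, rng_seed=12)
    a2 = seeding.select_greedy_kkt(G, endow, behaviors3, [1, 1, 0],
                                   spread_runs=50, rng_seed=12)
    assert a1.seed_sets == a2.seed_sets


# ---------------------------------------------------------------- variants

HEURISTIC_NAMES = ["random", "degree_nt", "degree_t", "degree_knap",
                   "degree_resource", "ciw_rank", "ciw_margin", "eia"]


@pytest.mark.parametrize("name", HEURISTIC_NAMES)
def test_heuristics_fill_budget_and_respect_variant(name, behaviors3):
    from rcdiff.graphs import gen_preferential_attachment
    G = gen_preferential_attachment(40, 3)
    rng = np.random.default_rng(4)
    endow = Endowments(rng.random(40), rng.random((40, 3)))
    budget = np.array([3, 3, 3])
    strat = seed_strategy(name, budget)
    assn = strat(G, endow.copy(), np.random.default_rng(8))
    assert assn.counts().tolist() == [3, 3, 3]
    # affordability after top-up
    for v in assn.nodes():
        pinned_cost = sum(behaviors3.costs[i] for i in assn.pinned_behaviors(v))
        assert endow.resource[v] + assn.topped_up.get(v, 0.0) >= pinned_cost - 1e-9
    if name in ("degree_nt", "degree_knap"):  # no-top-up rules
        assert assn.topped_up == {}
    if name != "degree_knap":  # single-behavior variants
        for v in assn.nodes():
            assert len(assn.pinned_behaviors(v)) == 1
    # determinism under an identical rng
    assn2 = strat(G, endow.copy(), np.random.default_rng(8))
    assert assn2.seed_sets == assn.seed_sets


def test_multi_behavior_space_contains_single_behavior_space():
    """The M variant's best achievable participation is at least the S
    variant's: evaluated exhaustively with common random thresholds."""
    bs = BehaviorSet([0.3, 0.6], [0.3, 0.6])
    G = nx.path_graph(4)
    rng = np.random.default_rng(20)
    endow = Endowments(rng.random(4), np.zeros((4, 2)))
    ga = _engine.GraphArrays.from_graph(G)
    R = 400
    theta = rng.random((R, 4, 2))

    def sigma(v0, v1):
        A0 = np.zeros((R, 4, 2), dtype=bool)
        A0[:, v0, 0] = True
        A0[:, v1, 1] = True
        r_eff = endow.resource.copy()
        r_eff[v0] = max(r_eff[v0], 0.3)
        need1 = 0.6 + (0.3 if v0 == v1 else 0.0)
        r_eff[v1] = max(r_eff[v1], need1)
        A, _, _ = _engine.run_sticky(ga, bs.costs, bs.utilities, 0.5,
                                     r_eff, theta, A0, 50)
        return A.any(axis=-1).sum(axis=-1).mean()

    best_S = max(sigma(a, b) for a, b in itertools.permutations(range(4), 2))
    best_M = max(sigma(a, b) for a, b in itertools.product(range(4), repeat=2))
    assert best_M >= best_S

    # the M variant machinery can express node reuse across behaviors
    assn = seeding.select_random(nx.path_graph(2), rich_endowments(2, 2), bs,
                                 [2, 2], "M-T", 1)
    assert assn.counts().tolist() == [2, 2]
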