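# Methods

## Model

Behaviors spread over an undirected simple graph G = (V, E).  The k
behaviors carry intrinsic costs c₁ ≤ … ≤ c_k and utilities u₁, …, u_k, all
in [0, 1]; cost and utility are properties of the behavior, not of the
adopter.  Each individual v holds a fixed resource r(v) and a private
threshold θᵢ(v) per behavior, both i.i.d. U(0, 1) by default (`sample_endowments`).
Influence weights are row-normalized: neighbor w pushes on v with weight
b_{v,w} = 1/|N(v)|, so incoming weights sum to one and the threshold part
of the dynamics is the classic Linear Threshold rule.  The social signal is
lᵢ(v) = Σ_{w∈N(v), w adopted i} b_{v,w} and the payoff of behavior i at v
is pᵢ(v) = w·uᵢ + (1 − w)·lᵢ(v).

Per synchronous epoch each node forms its candidate set — behaviors whose
signal meets the threshold (lᵢ ≥ θᵢ; the boundary has measure zero under
continuous thresholds) and whose cost fits the budget — and adopts the
payoff-maximizing feasible subset.  The knapsack is solved exactly by
enumerating all 2^k subsets (k is small by design); ties break toward the
lower total cost, then the lexicographically smallest index set, so runs
are reproducible.

Two dynamics are implemented (`run_diffusion(mode=...)`):

* **sticky** — progressive adoption: behaviors are never dropped, each
  adoption reduces the residual budget r(v) − s(v), and the process
  terminates when no node changes (at most |V|·k epochs).  This is the
  variant with the submodularity theory behind the greedy algorithm.
* **reevaluate** — each epoch every node re-solves its knapsack over all
  *eligible* behaviors against its full budget.  Already-adopted behaviors
  stay eligible without re-passing the threshold test (a node drops a
  behavior only when the knapsack displaces it with a better bundle), and
  seed-pinned behaviors are always retained.  The alternative reading —
  re-testing thresholds for adopted behaviors every epoch — collapses the
  all-nodes-seeded equilibrium utilization far below the values the
  acceptance computations reproduce, so the grandfathered rule is the one
  retained.  Oscillation is
  possible in principle; runs terminate at a state fixed point or after
  `max_epochs` (default 1000) with `converged=False`.  In practice all
  study-condition runs reach a fixed point within a few epochs.

The payoff weight w defaults to 0.5 and is recorded in every result row.
Under the study conditions (u = c) the metrics are essentially insensitive
to w (checked at w ∈ {0, 0.5, 1}), because with uniform thresholds any
affordable candidate has positive payoff and participation is driven by
the threshold rule, not by payoff ordering.

## Live-edge oracle

`live_edge` implements the equivalent pre-sampled formulation of the sticky
process: before diffusion each node draws, with replacement, one incoming
live edge per individually affordable behavior (κ(v) = |{j : c_j ≤ r(v)}|
slots, computed from the *original* r(v)); behavior j becomes a candidate
only when the slot-j live neighbor has adopted j.  Payoffs in the knapsack
step use the full-neighborhood signal, matching the threshold model.
Marginalized over edge draws the process reproduces the sticky dynamics'
distribution over active sets (checked per node within 3 Monte-Carlo SE on
small fixtures), and for a fixed draw the participation is a coverage
function — monotone and submodular, checked exhaustively — which yields the
(1 − 1/e) guarantee of greedy seed selection.  Expected participation is
#P-hard to compute exactly, hence the Monte-Carlo estimators.

## Seed selection

All selectors support the S/M (single vs multiple behaviors per seed) and
T/NT (top-up vs affordability-restricted) variants; the comparison tables
use S-T.  Topping up sets r(v) to the pinned cost when the seed falls
short (never additive), and topped-up resource enters the utilization
denominator.  Argmax ties are broken uniformly at random with the run's
generator.  The ranked heuristics (degree+resource, CIW) take per-behavior
top-b[i] lists, resolve cross-behavior collisions by a uniform pick, and
refill still-short behaviors from the next-ranked nodes.  The CIW
max-margin hill climb recomputes e_i(v) = 1 + Σ_{u∈N(v), r(u)≥c_i} 1/|N(u)|
excluding current seeds, then discounts each chosen node's *actual*
contribution from its neighbors' scores (a resource-poor neighbor
contributed 0, so 0 is removed — the score stays consistent with its
definition).

The EIA heuristic commits (behavior, node) pairs by exact marginal expected
one-step adoption.  With U(0, 1) thresholds, behavior j is a candidate at
v independently with probability lⱼ(v)·1[c_j ≤ r(v)]; the adoption
probability is computed exactly by enumerating all 2^k candidate sets and
their knapsack outcomes.  Only non-seed nodes are counted.  Marginal gains
are evaluated locally (adding a seed only perturbs its neighbors'
signals), which makes per-run reselection affordable even at n = 500.

The greedy approximation estimates the sticky-dynamics participation of
S ∪ {v} by Monte Carlo (default 1000 simulations; the table-5 scale uses
200) for every candidate, behavior by behavior, committing the globally
best pair.  One threshold batch is shared by all candidates of a scan
(common random numbers), which removes between-candidate sampling noise
from the argmax; candidates are simulated in vectorized batches.  A
`spread_estimator` hook lets tests replace the Monte-Carlo step with exact
enumeration.

## Estimation regimes and problem sizes

`metrics_mc.estimate` averages participation, adoption and utilization over
independent runs under two regimes: *threshold average* (topology fixed;
endowments resampled per run, seed selection re-applied per run, since
selection reads r) and *network average* (endowments fixed; topology
regenerated per run).  The two agree within Monte-Carlo error on the
random-graph ensembles used here, which the suite checks on all three
generators.  For selection algorithms too expensive to re-run per draw
(the simulation greedy), `reselect="seeds_frozen"` selects once per
topology and then averages over endowment resamples with the seeds' top-ups
re-derived — this keeps greedy rows on the same averaging basis as the
cheap heuristics; `reselect="thresholds_only"` additionally freezes the
resources (used against exact enumeration oracles).

The default study conditions are: three behaviors with costs
(0.2, 0.5, 0.7) and u = c; synthetic topologies of 500 nodes
(preferential-attachment tree with degree-proportional attachment,
ring-lattice small world rewired with p = 0.2, spatially clustered with
mean degree 10); seed fraction α = 0.1 rounded up to a multiple of k
(b = 51), distributed uniformly unless swept.  The reference experiments
use 5000 runs; the packaged acceptance computations use three independent
topology draws × 167 runs (~500 pooled) per configuration, which puts the
Monte-Carlo standard errors at the third decimal of the utilization
metrics, and n = 100 with b = 9 for the greedy comparison.

The spatially clustered generator places nodes uniformly in the unit
square and inserts the globally closest pairs until the target mean degree
is reached; it reproduces the target mean degree (within 2% for n ≥ 100)
and high clustering, but is one reasonable construction of a spatially
clustered network rather than a canonical algorithm.  The preferential-attachment
rule attaches strictly proportionally to degree: a smoothed (degree + 1)
variant was evaluated and systematically flattens the hubs, shifting every
heuristic-comparison cell away from the reported values.

## Known limitations

* The synthetic generators emulate the study's topology classes, not any
  particular empirical network; passing tests demonstrate fidelity to the
  model under i.i.d. U(0, 1) endowments, not validity on real adoption
  data.  Real-network (collaboration graph) columns require the external
  edge-list file and are not part of the packaged runs.
* Exact metric computation is limited to instances small enough to
  enumerate live-edge configurations; everything else is Monte Carlo with
  reported standard errors.
* Costs/utilities are homogeneous across individuals by design; per-edge
  weights other than 1/|N(v)| and asynchronous updates are out of scope.
* Subset-sum utilization points are merged with tolerance 1e-12 to absorb
  float collisions (0.2 + 0.5 vs 0.7); costs are compared against budgets
  with a 1e-9 slack everywhere.
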