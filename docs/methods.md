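# Methods

## Model

A sharing network is a simple directed graph on `N` nodes with a non-empty
hunter set `H`.  Per time step each hunter independently hunts with
probability `ph`; a success creates a package of `F` units that performs a
random walk: the hunter eats one unit, then the package makes `F−1` transfer
steps, each to a uniformly random out-neighbor of the current holder, halting
early at nodes with no out-neighbors, with one unit eaten at every node it
visits.  A node "eats" in a step if at least one package visits it.

Assumptions: packages from different hunters are independent; a node needs
only one unit per step (multiple visits in a step are not distinguished);
self-loops are disallowed; hunters always eat from their own successful hunt.

## Exact eating probabilities

For a fixed target node `v`, let `g_t(u)` be the probability that a package
currently at `u` with `t` transfer steps remaining visits `v` at some point.
Then `g_0(u) = [u = v]` and `g_t(u) = 1` if `u = v`, otherwise the mean of
`g_{t−1}` over the out-neighbors of `u` (0 for sinks).  The per-hunt
first-visit probability is `q(h, v) = g_{F−1}(h)`, and across independent
hunters

```
pe(v) = 1 − ∏_{h ∈ H} (1 − ph · q(h, v)).
```

This is `O(N·F·|A|)` per network and is validated in the test suite against
a walk-enumeration oracle and against direct Monte-Carlo simulation of the
protocol (`simulate_events`).

## Run-count distribution and risk of death

Over a lifetime of `n` steps a node dies if it experiences `k` consecutive
foodless steps.  `G_{n,k}` counts maximal runs of at least `k` failures
(failure probability `q = 1 − pe` per step); its maximum value is
`⌊(n+1)/(k+1)⌋` (91 for `n=1000, k=10`).

Two equivalent routes are implemented:

- **Markov-chain embedding** (`run_count_distribution`): state = (current
  run length capped at `k`, runs counted so far); one `O(k·gmax)` sparse
  update per step gives the exact pmf.
- **Closed-form moments** (`exact_run_moments`): from the indicator
  decomposition of maximal-run starts,
  `E[G] = q^k (1 + (n−k) p)` and
  `E[G²] = E[G] + 2 q^{2k} p (c₁ + p·(n−2k−1)(n−2k)/2)` with `c₁ = n−2k`
  (terms clipped at 0 when `n < 2k`), where `p = 1 − q`.

The moments route is the default because it is `O(1)` and the optimizer
evaluates `RV` for every node of every candidate network; the two routes are
asserted equal to `1e-9` (property-based test over random `(n, k, q)`), and
both are checked against exhaustive enumeration at small `n` and against
Monte-Carlo run counting at the working scale.  Results are memoized on
`(pe, n, k)` with `pe` rounded to 12 decimals.

The risk function is

```
RV(pe) = ((k+1)/(n+1)) · (E[G_{n,k}] + σ[G_{n,k}]),
```

so `RV(0) = (k+1)/(n+1)`, `RV(1) = 0`, with an interior maximum.  For
`n=1000, k=10` the maximizer found by bounded scalar minimization over a
bracketing grid is `pe* = 0.089992…`; the mean-only part alone is maximized
at `(n−2k)/((n−k)(k+1)) = 0.0900…`, confirming the location.

## Costs and conventions

- `WEF` = population standard deviation (divisor `N`) of the eating
  probabilities of **all** nodes, hunters included.
- `RV` cost = mean of `RV(pe(v))` over **all** nodes, hunters included.

Both conventions are forced by the worked reciprocity examples: the profiles
`D1 = (0.08, 0.02×4)`, `D2 = (0.08, 0.02, 0.035×3)`, `D3 = (0.08, 0.035×4)`
reproduce the reference cost pairs (RV, WEF) = (0.261, 0.024),
(0.315, 0.020), (0.332, 0.018) only under these choices.

**Printed-precision agreement.**  The exact values are RV(D2) = 0.314948
(rounds to the printed 0.315) but RV(D3) = 0.332850 and pe* = 0.089992,
which match their printed counterparts 0.332 and 0.0899 only under
truncation.  Tests and acceptance checks therefore assert agreement within
one unit in the last printed digit; the acceptance script reports raw
values.

Dominance is strict-componentwise-≤ with at least one strict inequality;
`pareto_filter` is stable, keeps duplicates of retained vectors, and rejects
empty input.

## Optimization

Individuals are arc sets over a fixed `(N, nh)` scaffold with hunters
`0..nh−1`; the initial population draws each individual's arc density
uniformly from `init_density_range`.  Mutation toggles one uniformly random
ordered pair (always exactly one change).  Selection is size-`t` tournament
over `λ = lambda_ratio·μ` offspring with comma (non-elitist) replacement.
Full-scale defaults are `μ=1000, λ/μ=8, t=12, 200` generations; tests use
oracle-checked desk scales (`μ≈30–60`, `N=4–12`).

**Hall of fame (design choice).**  With a mandatory one-toggle mutation,
comma selection can never retain a visited optimum: every offspring of an
optimum differs from it by one arc.  The search therefore maintains a
bounded best-seen archive (single-objective: top-`hall_of_fame_size` by
criterion value; multi-objective: a nondominated archive), in the spirit of
the hall-of-fame facilities of standard EA toolkits, and the final answer is
screened from the archive together with the last population.

Post-processing: candidates are screened for exact local minimality (no
single arc toggle strictly improves the criterion, tolerance `1e-12`),
reduced to canonical form (arcs whose source is unreachable from every
hunter within `F−2` transfer steps are dropped — provably cost-preserving),
and deduplicated by a signature built from the sorted hunter/non-hunter
eating profiles and the cost pair rounded to 9 decimals.

`brute_force_optima` enumerates all `2^(N(N−1))` arc sets for `N ≤ 5` and
returns exact single-criterion minima, their argmin sets, and the exact
Pareto front.  Acceptance tests require the evolutionary search to recover
the exact global minimum in ≥ 9/10 seeds and ≥ 95 % of the exact front.

## Network features

The feature battery includes degree statistics, strongly-connected-component
count, mean local clustering (undirected projection), pair-based
reciprocity, in/out degree assortativity over arcs (NaN when degenerate),
arc-type counts (hunter→hunter, non-hunter→non-hunter, mixed), eating-profile
statistics, and the two costs.

Modularity is the directed Newman–Leicht form
`Q = (1/m) Σ_{uv} (A_uv − k^out_u k^in_v / m) δ(c_u, c_v)`, maximized by a
greedy node-move search with seeded random restarts (deterministic given
`seed`; NaN for arcless networks; verified against exhaustive Bell-number
enumeration at `N=6`).  Note that a single arc with both endpoints in
singleton blocks has `Q = 0` exactly (the degree products vanish), not
`Q < 0`; a 2-cycle split into singletons gives `Q = −0.5`.  The
average-intra-partition-clustering feature averages, over blocks of the best
partition, the mean local clustering of the block's nodes within the induced
subgraph.

## I/O and generators

Networks are read/written as TSV edge lists (`source<TAB>target`, 0-based
ids, hunter ids in a `<stem>.hunters` sidecar) or GraphML with a boolean
`hunter` node attribute.  Node ids are normalized to `0..N−1` in ascending
numeric order, so files already using contiguous 0-based ids round-trip
unchanged.  Parse errors carry line numbers.

`random_network(N, arc_prob, nh, seed)` draws each ordered pair
independently; the regime-shift analyses sample **uniform** random digraphs
(`arc_prob = 0.5`), i.e. uniformly over all simple digraphs on `N` nodes.
The sweep driver runs the optimizers over a `(ph, F, nh)` grid, labels cells
by food-supply regime (`F·nh ≤ N` = "low"), and writes JSON-lines optima
plus a CSV feature table; every stored record re-evaluates exactly to its
stored costs.

## Limitations

- Exhaustive oracles stop at `N = 5` (`2^20` networks); beyond that only
  local-minimality and cross-seed consistency are checkable.
- The greedy modularity search is exact only where verified (`N ≤ 6`
  exhaustively); at larger `N` it is a heuristic with restarts.
- Evolutionary results at full scale (`N` in the hundreds) are supported by
  the desk-scale oracle equivalences, not re-verified at that scale here.
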