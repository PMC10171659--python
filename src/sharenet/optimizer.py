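"""Evolutionary search for optimal sharing networks.

Single-criterion optima are *local minima*: networks whose criterion value no
single-arc toggle (add or remove one ordered pair) can strictly decrease.
The search is a (mu, lambda) evolution strategy — offspring-only (comma)
selection, one arc-toggle mutation per offspring, size-``t`` tournaments —
with defaults mu=1000, lambda/mu=8, t=12 chosen for high selective pressure.
The multi-objective case replaces the tournament by NSGA-II selection
(nondominated rank, then crowding distance) with deterministic tie-breaking,
and returns the first front of the final population.

Networks differing only in arcs that no feasible food walk can traverse have
identical costs; ``canonical_reduce`` strips such arcs, and deduplication
uses a signature built from the role-split eating-probability multiset and
the rounded cost pair (a documented approximation to a full isomorphism
quotient).

Exhaustive enumeration over all ``2^(N(N-1))`` digraphs (``brute_force_optima``)
provides exact global minima and Pareto fronts at tiny ``N`` as an oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .criteria import CostVector, cost_vector, dominates, rv_cost, wef_cost
from .sharing_model import ModelParams, SharingNetwork, eating_probabilities

__all__ = [
    "EvolutionConfig",
    "Individual",
    "mutate",
    "canonical_reduce",
    "signature",
    "find_improving_toggle",
    "is_local_minimum",
    "evolve_single",
    "nondominated_sort",
    "crowding_distance",
    "evolve_multi",
    "brute_force_optima",
    "random_digraph_population",
]

BRUTE_FORCE_MAX_N = 5


@dataclass(frozen=True)
class EvolutionConfig:
    """Knobs of the (mu, lambda) evolution strategy."""

    mu: int = 1000
    lambda_ratio: int = 8
    tournament_size: int = 12
    generations: int = 200
    seed: int = 0
    N: int = 12
    nh: int = 2
    init_density_range: tuple[float, float] = (0.05, 0.5)
    hall_of_fame_size: int = 100

    def __post_init__(self) -> None:
        if self.mu < 2:
            raise ValueError("mu must be >= 2")
        if self.lambda_ratio < 1:
            raise ValueError("lambda_ratio must be >= 1")
        if not 2 <= self.tournament_size <= self.mu * self.lambda_ratio:
            raise ValueError("tournament_size must be in [2, mu * lambda_ratio]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 1 <= self.nh <= self.N:
            raise ValueError("need 1 <= nh <= N")


@dataclass(frozen=True)
class Individual:
    network: SharingNetwork
    costs: CostVector
    signature: tuple = field(default=())


def _all_pairs(n: int) -> list[tuple[int, int]]:
    return [(u, v) for u in range(n) for v in range(n) if u != v]


def mutate(net: SharingNetwork, rng: np.random.Generator) -> SharingNetwork:
    """Toggle one uniformly chosen ordered pair: add the arc if absent,
    remove it if present.  Hunters are untouched; the result stays loop-free
    and simple by construction."""
    pairs = _all_pairs(net.n_nodes)
    u, v = pairs[rng.integers(len(pairs))]
    arcs = set(net.arcs)
    if (u, v) in arcs:
        arcs.remove((u, v))
    else:
        arcs.add((u, v))
    return net.with_arcs(arcs)


def _reachable_within(net: SharingNetwork, depth: int) -> set[int]:
    """Nodes at directed distance <= depth from some hunter."""
    if depth < 0:
        return set()
    adj = net.out_neighbors()
    seen = set(net.hunters)
    frontier = set(net.hunters)
    for _ in range(depth):
        frontier = {w for u in frontier for w in adj[u]} - seen
        if not frontier:
            break
        seen |= frontier
    return seen


def canonical_reduce(net: SharingNetwork, params: ModelParams) -> SharingNetwork:
    """Drop arcs that lie on no feasible food walk.

    A package makes at most ``F - 1`` transfers, so arc ``(u, v)`` can carry
    food only if ``u`` holds a package with units left, i.e. ``u`` is within
    ``F - 2`` steps of a hunter.  Removing the other arcs provably leaves the
    eating profile — hence both costs — unchanged.  Node set is preserved.
    """
    keep_sources = _reachable_within(net, params.F - 2)
    return net.with_arcs({(u, v) for (u, v) in net.arcs if u in keep_sources})


def signature(net: SharingNetwork, params: ModelParams, costs: CostVector | None = None) -> tuple:
    """Dedup key: sorted pe multisets split by hunter role + rounded costs."""
    profile = eating_probabilities(net, params)
    if costs is None:
        costs = CostVector(rv_cost(profile, params.n, params.k), wef_cost(profile))
    h_pe = tuple(sorted(round(profile[v], 9) for v in net.hunters))
    c_pe = tuple(sorted(round(profile[v], 9) for v in net.nodes if v not in net.hunters))
    return (h_pe, c_pe, round(costs.rv, 9), round(costs.wef, 9))


def _criterion_value(costs: CostVector, criterion: str) -> float:
    if criterion == "rv":
        return costs.rv
    if criterion == "wef":
        return costs.wef
    raise ValueError(f"criterion must be 'rv' or 'wef', got {criterion!r}")


def find_improving_toggle(
    net: SharingNetwork, params: ModelParams, criterion: str
) -> tuple[int, int] | None:
    """First single-arc toggle (in lexicographic pair order) that strictly
    decreases the criterion, or None if the network is a local minimum."""
    current = _criterion_value(cost_vector(net, params), criterion)
    arcs = set(net.arcs)
    for u, v in _all_pairs(net.n_nodes):
        trial = arcs ^ {(u, v)}
        value = _criterion_value(cost_vector(net.with_arcs(trial), params), criterion)
        if value < current - 1e-12:
            return (u, v)
    return None


def is_local_minimum(net: SharingNetwork, params: ModelParams, criterion: str) -> bool:
    return find_improving_toggle(net, params, criterion) is None


def random_digraph_population(config: EvolutionConfig, rng: np.random.Generator) -> list[SharingNetwork]:
    """Initial population: uniform random digraphs with a per-individual arc
    density drawn from ``init_density_range``; hunters are nodes 0..nh-1."""
    hunters = frozenset(range(config.nh))
    pairs = _all_pairs(config.N)
    lo, hi = config.init_density_range
    population = []
    for _ in range(config.mu):
        density = rng.uniform(lo, hi)
        mask = rng.random(len(pairs)) < density
        arcs = frozenset(p for p, m in zip(pairs, mask) if m)
        population.append(SharingNetwork(config.N, arcs, hunters))
    return population


class _CostCache:
    """Memoizes cost evaluation on the arc set (hunters/params fixed per run)."""

    def __init__(self, params: ModelParams):
        self.params = params
        self._cache: dict[frozenset, CostVector] = {}

    def __call__(self, net: SharingNetwork) -> CostVector:
        key = net.arcs
        hit = self._cache.get(key)
        if hit is None:
            hit = self._cache[key] = cost_vector(net, self.params)
        return hit


def evolve_single(
    params: ModelParams, config: EvolutionConfig, criterion: str
) -> list[Individual]:
    """(mu, lambda)-ES for one criterion; returns deduplicated local minima.

    Each generation every parent spawns ``lambda_ratio`` one-toggle mutants;
    the next generation is chosen by ``mu`` size-``t`` tournaments (with
    replacement) over the offspring pool only.  Ties break toward the lower
    cost, then the earlier insertion index.  Because mutation always toggles
    an arc, a comma-selected population cannot retain an optimum it has
    visited, so a bounded hall of fame records the best distinct networks
    seen; after the final generation the union of population and hall of
    fame is screened with ``is_local_minimum`` and deduplicated by signature.
    """
    _criterion_value(CostVector(0.0, 0.0), criterion)  # validate early
    rng = np.random.default_rng(config.seed)
    evaluate = _CostCache(params)
    parents = random_digraph_population(config, rng)
    hof: dict[frozenset, tuple[float, SharingNetwork]] = {}
    for _ in range(config.generations):
        offspring = [
            mutate(parent, rng)
            for parent in parents
            for _ in range(config.lambda_ratio)
        ]
        values = [_criterion_value(evaluate(child), criterion) for child in offspring]
        for child, value in zip(offspring, values):
            if child.arcs not in hof:
                hof[child.arcs] = (value, child)
        if len(hof) > 4 * config.hall_of_fame_size:
            kept = sorted(hof.items(), key=lambda kv: kv[1][0])[: config.hall_of_fame_size]
            hof = dict(kept)
        next_parents = []
        for _ in range(config.mu):
            contenders = rng.integers(len(offspring), size=config.tournament_size)
            best = min(contenders, key=lambda i: (values[i], i))
            next_parents.append(offspring[best])
        parents = next_parents
    finalists = sorted(hof.items(), key=lambda kv: kv[1][0])[: config.hall_of_fame_size]
    candidates = {net.arcs: net for _, (_, net) in finalists}
    candidates.update({net.arcs: net for net in parents})
    survivors: dict[tuple, Individual] = {}
    for net in candidates.values():
        costs = evaluate(net)
        sig = signature(net, params, costs)
        if sig in survivors:
            continue
        if is_local_minimum(net, params, criterion):
            reduced = canonical_reduce(net, params)
            survivors[sig] = Individual(reduced, costs, sig)
    return sorted(
        survivors.values(),
        key=lambda ind: _criterion_value(ind.costs, criterion),
    )


def nondominated_sort(costs: list) -> list[list[int]]:
    """Partition indices into Pareto fronts F1, F2, ... (fast nondominated sort)."""
    m = len(costs)
    dominated_by: list[list[int]] = [[] for _ in range(m)]
    dom_count = [0] * m
    for i, j in itertools.combinations(range(m), 2):
        if dominates(costs[i], costs[j]):
            dominated_by[i].append(j)
            dom_count[j] += 1
        elif dominates(costs[j], costs[i]):
            dominated_by[j].append(i)
            dom_count[i] += 1
    fronts = []
    current = [i for i in range(m) if dom_count[i] == 0]
    while current:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = sorted(nxt)
    return fronts


def crowding_distance(costs: list) -> list[float]:
    """NSGA-II crowding distance within one front (2 objectives)."""
    m = len(costs)
    if m <= 2:
        return [float("inf")] * m
    distance = [0.0] * m
    for dim in range(2):
        order = sorted(range(m), key=lambda i: costs[i][dim])
        lo, hi = costs[order[0]][dim], costs[order[-1]][dim]
        distance[order[0]] = distance[order[-1]] = float("inf")
        span = hi - lo
        if span <= 0:
            continue
        for a in range(1, m - 1):
            distance[order[a]] += (costs[order[a + 1]][dim] - costs[order[a - 1]][dim]) / span
    return distance


def evolve_multi(
    params: ModelParams, config: EvolutionConfig
) -> tuple[list[Individual], list[CostVector]]:
    """(mu, lambda) scheme with NSGA-II offspring selection.

    Selection ranks the offspring pool by nondominated front, then by
    descending crowding distance, breaking remaining ties deterministically
    by signature then insertion index.  A bounded nondominated archive
    accumulates the front across generations (comma selection with forced
    mutation cannot retain visited optima on its own); the returned set is
    the nondominated subset of archive plus final population, after
    canonical reduction and signature dedup, with its cost vectors.
    """
    rng = np.random.default_rng(config.seed)
    evaluate = _CostCache(params)
    parents = random_digraph_population(config, rng)
    archive: dict[frozenset, CostVector] = {}
    archive_nets: dict[frozenset, SharingNetwork] = {}
    for _ in range(config.generations):
        offspring = [
            mutate(parent, rng)
            for parent in parents
            for _ in range(config.lambda_ratio)
        ]
        costs = [evaluate(child) for child in offspring]
        fronts = nondominated_sort(costs)
        for i in fronts[0]:
            key = offspring[i].arcs
            if key not in archive:
                archive[key] = costs[i]
                archive_nets[key] = offspring[i]
        if len(archive) > 4 * config.hall_of_fame_size:
            keys = list(archive)
            arch_costs = [archive[k] for k in keys]
            keep_idx = nondominated_sort(arch_costs)[0][: config.hall_of_fame_size]
            keep = {keys[i] for i in keep_idx}
            archive = {k: archive[k] for k in keep}
            archive_nets = {k: archive_nets[k] for k in keep}
        selected: list[int] = []
        for front in fronts:
            if len(selected) + len(front) <= config.mu:
                selected.extend(front)
            else:
                dist = crowding_distance([costs[i] for i in front])
                order = sorted(
                    range(len(front)),
                    key=lambda a: (
                        -dist[a],
                        signature(offspring[front[a]], params, costs[front[a]]),
                        front[a],
                    ),
                )
                selected.extend(front[a] for a in order[: config.mu - len(selected)])
            if len(selected) >= config.mu:
                break
        parents = [offspring[i] for i in selected]
    pool: dict[frozenset, SharingNetwork] = dict(archive_nets)
    pool.update({net.arcs: net for net in parents})
    nets = list(pool.values())
    pool_costs = [evaluate(net) for net in nets]
    first_front = nondominated_sort(pool_costs)[0]
    seen: dict[tuple, Individual] = {}
    for i in first_front:
        sig = signature(nets[i], params, pool_costs[i])
        if sig not in seen:
            seen[sig] = Individual(canonical_reduce(nets[i], params), pool_costs[i], sig)
    individuals = sorted(seen.values(), key=lambda ind: ind.costs)
    return individuals, [ind.costs for ind in individuals]


def brute_force_optima(N: int, hunters, params: ModelParams) -> dict:
    """Exact optima by enumerating all loop-free simple digraphs on N nodes.

    Returns global minima per criterion and the exact Pareto front/set.
    Refuses N above the enumeration bound (2^(N(N-1)) digraphs).
    """
    if N > BRUTE_FORCE_MAX_N:
        raise ValueError(
            f"N={N} exceeds the enumeration bound N <= {BRUTE_FORCE_MAX_N} "
            f"(2^(N(N-1)) digraphs)"
        )
    hunters = frozenset(hunters)
    pairs = _all_pairs(N)
    results: list[tuple[SharingNetwork, CostVector]] = []
    for mask in range(1 << len(pairs)):
        arcs = frozenset(pairs[i] for i in range(len(pairs)) if mask >> i & 1)
        net = SharingNetwork(N, arcs, hunters)
        results.append((net, cost_vector(net, params)))
    all_costs = [c for _, c in results]
    rv_best = min(c.rv for c in all_costs)
    wef_best = min(c.wef for c in all_costs)
    front_idx = [
        i for i, c in enumerate(all_costs)
        if not any(dominates(d, c) for d in all_costs)
    ]
    front_costs = sorted({(round(all_costs[i].rv, 12), round(all_costs[i].wef, 12)) for i in front_idx})
    return {
        "rv_min": rv_best,
        "wef_min": wef_best,
        "rv_argmin_networks": [n for n, c in results if c.rv <= rv_best + 1e-12],
        "wef_argmin_networks": [n for n, c in results if c.wef <= wef_best + 1e-12],
        "pareto_front": [CostVector(*c) for c in front_costs],
        "pareto_set": [results[i][0] for i in front_idx],
    }
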