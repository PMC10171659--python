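"""Tests for mutation, canonical reduction, local minimality and evolution."""

import numpy as np
import pytest

from sharenet import (
    EvolutionConfig,
    ModelParams,
    SharingNetwork,
    brute_force_optima,
    canonical_reduce,
    cost_vector,
    crowding_distance,
    dominates,
    evolve_multi,
    evolve_single,
    find_improving_toggle,
    is_local_minimum,
    mutate,
    nondominated_sort,
    pareto_filter,
    random_network,
)

PARAMS_N4 = ModelParams(ph=0.3, F=3)


class TestMutate:
    def test_empty_network_gains_one_arc(self):
        net = SharingNetwork(3, frozenset(), frozenset({0}))
        out = mutate(net, np.random.default_rng(0))
        assert len(out.arcs) == 1 and out.hunters == net.hunters

    def test_complete_digraph_loses_one_arc(self):
        arcs = {(u, v) for u in range(4) for v in range(4) if u != v}
        net = SharingNetwork(4, frozenset(arcs), frozenset({0}))
        out = mutate(net, np.random.default_rng(1))
        assert len(out.arcs) == len(arcs) - 1

    def test_always_exactly_one_toggle(self):
        rng = np.random.default_rng(2)
        net = random_network(5, 0.3, 2, seed=3)
        for _ in range(50):
            out = mutate(net, rng)
            assert len(net.arcs ^ out.arcs) == 1
            net = out

    def test_seeded_sequence_is_reproducible(self):
        net = random_network(5, 0.3, 2, seed=3)
        seq_a = [mutate(net, np.random.default_rng(9)).arcs for _ in range(5)]
        seq_b = [mutate(net, np.random.default_rng(9)).arcs for _ in range(5)]
        assert seq_a == seq_b


class TestCanonicalReduce:
    def test_preserves_costs_on_random_networks(self):
        params = ModelParams(ph=0.2, F=4)
        for seed in range(6):
            net = random_network(7, 0.3, 2, seed=seed)
            reduced = canonical_reduce(net, params)
            assert reduced.arcs <= net.arcs
            a, b = cost_vector(net, params), cost_vector(reduced, params)
            assert a == pytest.approx(b, abs=1e-12)

    def test_removes_arcs_unreachable_from_hunters(self):
        # arc 3->4 sits beyond any feasible walk from hunter 0 at F=2
        net = SharingNetwork(5, frozenset({(0, 1), (3, 4)}), frozenset({0}))
        reduced = canonical_reduce(net, ModelParams(ph=0.5, F=2))
        assert reduced.arcs == frozenset({(0, 1)})

    def test_worked_example_all_arcs_feasible(self, fig1):
        assert canonical_reduce(fig1, ModelParams(ph=0.2, F=5)).arcs == fig1.arcs

    def test_no_sharing_when_single_unit(self, fig1):
        assert canonical_reduce(fig1, ModelParams(ph=0.2, F=1)).arcs == frozenset()


class TestLocalMinimum:
    def test_all_hunters_empty_network_is_wef_minimum(self):
        net = SharingNetwork(4, frozenset(), frozenset(range(4)))
        assert is_local_minimum(net, PARAMS_N4, "wef")

    def test_agrees_with_exhaustive_neighborhood_check(self):
        # brute-force global minima must be local minima; a constructed
        # non-optimum must expose its improving toggle
        result = brute_force_optima(3, {0}, PARAMS_N4)
        for net in result["wef_argmin_networks"][:3]:
            assert is_local_minimum(net, PARAMS_N4, "wef")
        for net in result["rv_argmin_networks"][:3]:
            assert is_local_minimum(net, PARAMS_N4, "rv")

    def test_improving_toggle_reported(self):
        # ph=0.6 > pe*: feeding a starving consumer lowers mean RV, so the
        # empty 2-node network is not an RV local minimum
        net = SharingNetwork(2, frozenset(), frozenset({0}))
        params = ModelParams(ph=0.6, F=2)
        toggle = find_improving_toggle(net, params, "rv")
        assert toggle == (0, 1)
        assert not is_local_minimum(net, params, "rv")


class TestNondominatedSort:
    def test_chain_gives_singleton_fronts(self):
        fronts = nondominated_sort([(1, 1), (2, 2), (3, 3)])
        assert fronts == [[0], [1], [2]]

    def test_printed_triple_single_front(self):
        triple = [(0.261, 0.024), (0.315, 0.02), (0.332, 0.018)]
        assert nondominated_sort(triple) == [[0, 1, 2]]

    def test_agrees_with_repeated_pareto_peeling(self):
        rng = np.random.default_rng(11)
        vecs = [tuple(x) for x in rng.integers(0, 6, size=(40, 2))]
        fronts = nondominated_sort(vecs)
        remaining = list(enumerate(vecs))
        for front in fronts:
            layer = pareto_filter([v for _, v in remaining])
            expect = [i for i, v in remaining if not any(
                dominates(w, v) for _, w in remaining)]
            assert sorted(front) == sorted(expect)
            assert len(front) == len(layer)
            remaining = [(i, v) for i, v in remaining if i not in set(front)]
        assert not remaining

    def test_crowding_extremes_infinite(self):
        dist = crowding_distance([(0, 3), (1, 2), (2, 1), (3, 0)])
        assert dist[0] == dist[3] == float("inf")
        assert np.isfinite(dist[1]) and np.isfinite(dist[2])


def small_config(seed, N=4, nh=1, mu=30, generations=40):
    return EvolutionConfig(
        mu=mu, lambda_ratio=8, tournament_size=12,
        generations=generations, seed=seed, N=N, nh=nh,
    )


class TestEvolution:
    def test_wef_all_hunters_reaches_global_zero(self):
        config = small_config(seed=0, N=4, nh=4, generations=20)
        minima = evolve_single(ModelParams(ph=0.3, F=2), config, "wef")
        assert minima and min(ind.costs.wef for ind in minima) == pytest.approx(0.0, abs=1e-12)

    def test_seeded_run_is_bit_identical(self):
        config = small_config(seed=5, mu=20, generations=10)
        a = evolve_single(PARAMS_N4, config, "rv")
        b = evolve_single(PARAMS_N4, config, "rv")
        assert [i.network.arcs for i in a] == [j.network.arcs for j in b]
        assert [i.costs for i in a] == [j.costs for j in b]

    def test_single_criterion_finds_global_minimum(self):
        oracle = brute_force_optima(4, {0}, PARAMS_N4)
        minima = evolve_single(PARAMS_N4, small_config(seed=1), "wef")
        best = min(ind.costs.wef for ind in minima)
        assert best == pytest.approx(oracle["wef_min"], abs=1e-9)

    def test_multi_objective_front_nondominated_and_reduced(self):
        params = ModelParams(ph=0.08, F=4)
        individuals, front = evolve_multi(params, small_config(seed=2))
        assert front == pareto_filter(front)
        for ind in individuals:
            assert canonical_reduce(ind.network, params).arcs == ind.network.arcs
            assert cost_vector(ind.network, params) == pytest.approx(ind.costs, abs=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EvolutionConfig(mu=1)
        with pytest.raises(ValueError):
            EvolutionConfig(mu=10, lambda_ratio=1, tournament_size=50)
        with pytest.raises(ValueError):
            evolve_single(PARAMS_N4, small_config(seed=0), "unknown")


class TestBruteForce:
    def test_two_node_enumeration_by_hand(self):
        # 4 digraphs on {0,1}, hunter 0, ph=0.5, F=2: consumer pe is 0.5 iff
        # the arc 0->1 is present, else 0; so WEF = 0 exactly for the two
        # networks containing 0->1 and 0.25 for the other two
        params = ModelParams(ph=0.5, F=2)
        result = brute_force_optima(2, {0}, params)
        assert result["wef_min"] == pytest.approx(0.0, abs=1e-12)
        nets = result["wef_argmin_networks"]
        assert len(nets) == 2
        for net in nets:
            assert (0, 1) in net.arcs
            assert cost_vector(net, params).wef == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_front(self):
        a = brute_force_optima(4, {0}, PARAMS_N4)
        b = brute_force_optima(4, {0}, PARAMS_N4)
        assert a["pareto_front"] == b["pareto_front"]
        assert len(a["pareto_front"]) >= 1

    def test_refuses_large_instances(self):
        with pytest.raises(ValueError):
            brute_force_optima(6, {0}, PARAMS_N4)
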