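"""Topological sorting, block structure, kernels and exact stationary solutions."""

import numpy as np
import pytest
import scipy.linalg
import scipy.sparse as sp

import boolsteady as bs
from boolsteady.oracle import dense_transient
from boolsteady.solver import (
    KernelPair,
    _verify_kernels,
    build_left_kernel,
    build_right_kernel,
    condense_and_sort,
    reorder_blocks,
    terminal_distribution,
)
from conftest import TOY_EXACT, TOY_NODE_EXACT, toy_exact_vector


def _component_kernels(net, rates, comp=None, chain_reorder=False):
    table = bs.enumerate_transitions(net)
    K = bs.build_kinetic_matrix(table, rates, net)
    sorting = condense_and_sort(table, comp, chain_reorder=chain_reorder)
    N, B, T = reorder_blocks(K, sorting)
    R = build_right_kernel(sorting, T)
    L = build_left_kernel(R, N, B, sorting.u)
    idx = sorting.order - 1
    return sorting, K[np.ix_(idx, idx)].tocsc(), (N, B, T), KernelPair(R, L, sorting.u)


class TestCondenseAndSort:
    def test_toy_attractors_relabelled_to_last_positions(self, toy_table):
        sorting = condense_and_sort(toy_table)
        # attractor states 4, 5, 6 end up at sorted positions 6, 7, 8
        assert sorting.u == 5 and sorting.q == 3
        assert list(sorting.order[5:]) == [4, 5, 6]

    def test_toy_sccs_all_singletons(self, toy_table):
        sorting = condense_and_sort(toy_table)
        assert len(set(sorting.scc_id.values())) == 8

    def test_oscillator_single_terminal_scc(self, oscillator):
        sorting = condense_and_sort(bs.enumerate_transitions(oscillator))
        assert sorting.u == 0 and sorting.q == 1
        assert len(sorting.terminal_sccs[0]) == 4

    @pytest.mark.parametrize("seed", range(50))
    def test_arcs_between_sccs_always_point_forward(self, seed):
        net = bs.fixtures.random_bn(3 + seed % 4, 2, seed)
        table = bs.enumerate_transitions(net)
        sorting = condense_and_sort(table)
        pos = sorting.position()
        for s, t in zip(table.source, table.target):
            if sorting.scc_id[int(s)] != sorting.scc_id[int(t)]:
                assert pos[int(s)] < pos[int(t)]

    def test_terminal_states_occupy_trailing_positions(self, toy_table):
        sorting = condense_and_sort(toy_table)
        terminal = {int(s) for scc in sorting.terminal_sccs for s in scc}
        assert set(sorting.order[sorting.u:].tolist()) == terminal


class TestReorderBlocks:
    def test_toy_N_lower_triangular_T_zero(self, toy_K, toy_table):
        sorting = condense_and_sort(toy_table)
        N, B, T = reorder_blocks(toy_K, sorting)
        assert N.shape == (5, 5) and T.shape == (3, 3)
        assert sp.triu(N, k=1).nnz == 0          # acyclic → lower triangular
        assert T.nnz == 0                        # fixed points only
        assert B.shape == (3, 5)

    def test_oscillator_has_empty_transient_block(self, oscillator):
        rates = bs.TransitionRates.uniform(oscillator)
        table = bs.enumerate_transitions(oscillator)
        K = bs.build_kinetic_matrix(table, rates, oscillator)
        sorting = condense_and_sort(table)
        N, B, T = reorder_blocks(K, sorting)
        assert N.shape == (0, 0) and T.shape == (4, 4)
        assert np.allclose(T.toarray(), K.toarray()[np.ix_(sorting.order - 1,
                                                           sorting.order - 1)])

    @pytest.mark.parametrize("seed", range(10))
    def test_permutation_similarity_against_dense_oracle(self, seed):
        net = bs.fixtures.random_bn(4, 2, seed)
        rates = bs.TransitionRates.random(net, seed)
        table = bs.enumerate_transitions(net)
        K = bs.build_kinetic_matrix(table, rates, net)
        sorting = condense_and_sort(table)
        idx = sorting.order - 1
        P = np.eye(net.n_states)[idx]
        dense = P @ K.toarray() @ P.T
        N, B, T = reorder_blocks(K, sorting)
        u = sorting.u
        assert np.allclose(dense[:u, :u], N.toarray())
        assert np.allclose(dense[u:, :u], B.toarray())
        assert np.allclose(dense[u:, u:], T.toarray())
        assert np.allclose(dense[:u, u:], 0.0)


class TestTerminalDistribution:
    def test_two_state_cycle_detailed_balance(self):
        # rates a: 1->2 and b: 2->1 give stationary (b, a)/(a+b)
        a, b = 3.0, 1.0
        T = np.array([[-a, b], [a, -b]])
        assert np.allclose(terminal_distribution(T), [b / (a + b), a / (a + b)])
        T1 = np.array([[-1.0, 1.0], [1.0, -1.0]])
        assert np.allclose(terminal_distribution(T1), [0.5, 0.5])

    def test_four_state_ring_uniform_at_equal_rates(self, oscillator):
        rates = bs.TransitionRates.uniform(oscillator)
        table = bs.enumerate_transitions(oscillator)
        K = bs.build_kinetic_matrix(table, rates, oscillator)
        sorting = condense_and_sort(table)
        _, _, T = reorder_blocks(K, sorting)
        assert np.allclose(terminal_distribution(T), 0.25)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_strongly_connected_laplacians_match_eigen_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = 6
        W = rng.uniform(0.5, 2.0, size=(m, m))
        np.fill_diagonal(W, 0.0)
        # W[j, i] = rate i -> j over a complete graph: strongly connected
        T = W - np.diag(W.sum(axis=0))
        v = terminal_distribution(sp.csc_matrix(T))
        ns = scipy.linalg.null_space(T)
        assert ns.shape[1] == 1
        ref = np.abs(ns[:, 0]) / np.abs(ns[:, 0]).sum()
        assert np.allclose(v, ref, atol=1e-10)

    def test_rejects_non_closed_subgraph(self):
        T = np.array([[-2.0, 1.0], [1.0, -1.0]])   # leaks probability
        with pytest.raises(ValueError):
            terminal_distribution(T)


class TestKernels:
    def test_toy_right_kernel_structure(self, toy3, unit_rates):
        sorting, Kp, blocks, kernels = _component_kernels(toy3, unit_rates)
        R = kernels.R
        assert R.shape == (8, 3)
        dense = R.toarray()
        assert np.allclose(dense[:5, :], 0.0)            # Y block of zeros
        assert np.allclose(dense[5:, :], np.eye(3))      # V: 1s at positions 6,7,8
        assert np.allclose(np.asarray(abs(Kp @ R).max()), 0.0, atol=1e-12)

    def test_toy_absorption_probabilities_from_110(self, toy3, unit_rates):
        sorting, _, _, kernels = _component_kernels(toy3, unit_rates)
        pos = sorting.position()[7]                      # transient state [110]
        # attractor order is [011], [100], [101]
        assert np.allclose(kernels.X[:, pos], [1 / 3, 1 / 2, 1 / 6])

    def test_exit_rate_of_110_matches_symbolic_denominator(self, toy3, toy_table):
        # total exit rate of [110] is d_A + d_B + u_C (= 4 at u_C=2, others 1)
        rates = bs.TransitionRates.uniform(toy3).replace(u_C=2.0)
        K = bs.build_kinetic_matrix(toy_table, rates, toy3)
        assert K[6, 6] == -4.0

    def test_single_path_transient_absorbs_with_probability_one(self, toy3, unit_rates):
        sorting, _, _, kernels = _component_kernels(toy3, unit_rates)
        pos = sorting.position()[1]                      # [000] -> [100] only
        assert np.allclose(kernels.X[:, pos], [0.0, 1.0, 0.0])

    def test_absorption_columns_sum_to_one(self, toy3, unit_rates):
        _, _, _, kernels = _component_kernels(toy3, unit_rates)
        assert np.allclose(kernels.X.sum(axis=0), 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(30))
    def test_kernel_identities_on_random_models(self, seed):
        net = bs.fixtures.random_bn(3 + seed % 5, 2, seed)
        rates = bs.TransitionRates.random(net, seed + 1)
        table = bs.enumerate_transitions(net)
        K = bs.build_kinetic_matrix(table, rates, net)
        for comp in bs.split_subgraphs(table):
            _, Kp, _, kernels = _component_kernels(net, rates, comp)
            assert _verify_kernels(Kp, kernels) <= 1e-9

    def test_chain_reorder_gives_identical_solutions(self, oscillator):
        rates = bs.TransitionRates.random(oscillator, 5)
        x0 = bs.make_initial_condition(oscillator)
        plain = bs.ExactSolver(oscillator).solve(rates, x0)
        chained = bs.ExactSolver(oscillator, chain_reorder=True).solve(rates, x0)
        assert np.allclose(plain.x_star, chained.x_star, atol=1e-12)


class TestStationarySolution:
    def test_toy_uniform_initial_condition(self, toy3):
        result = bs.solve(toy3)
        probs = result.state_probabilities()
        for label, expected in TOY_EXACT.items():
            assert probs[label] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(result.x_star, toy_exact_vector(toy3), atol=1e-12)

    def test_point_mass_on_fixed_point_is_invariant(self, toy3):
        x0 = np.zeros(8)
        x0[3] = 1.0                                      # S_4 = [011]
        result = bs.solve(toy3, init=x0)
        assert np.allclose(result.x_star, x0, atol=1e-12)

    def test_point_mass_on_000_flows_to_100(self, toy3):
        x0 = np.zeros(8)
        x0[0] = 1.0
        result = bs.solve(toy3, init=x0)
        expected = np.zeros(8)
        expected[4] = 1.0                                # S_5 = [100]
        assert np.allclose(result.x_star, expected, atol=1e-12)

    def test_nonterminal_states_carry_no_stationary_mass(self, toy3):
        result = bs.solve(toy3)
        transient = [0, 1, 2, 6, 7]
        assert np.abs(result.x_star[transient]).max() <= 1e-9

    def test_attractor_probabilities_sum_to_one(self, toy3):
        result = bs.solve(toy3, rates=bs.TransitionRates.random(toy3, 9))
        assert sum(a.probability for a in result.attractors) == pytest.approx(1.0, abs=1e-9)

    def test_conservation_along_dense_trajectory(self, toy3, unit_rates, toy_K):
        # L·x(t) must be constant in t (checked at 5 time points)
        sorting, _, _, kernels = _component_kernels(toy3, unit_rates)
        x0 = np.full(8, 1 / 8)
        idx = sorting.order - 1
        ref = kernels.L @ x0[idx]
        for t in (0.0, 0.3, 1.0, 5.0, 20.0):
            xt = dense_transient(toy_K, x0, t)
            assert np.allclose(kernels.L @ xt[idx], ref, atol=1e-9)

    def test_node_probabilities_match_hand_derived_values(self, toy3):
        result = bs.solve(toy3)
        for name, expected in TOY_NODE_EXACT.items():
            assert result.node_probabilities[name] == pytest.approx(expected, abs=1e-12)
        assert all(0 <= p <= 1 for p in result.node_probabilities.values())

    def test_single_saturated_attractor_sets_all_nodes(self):
        net = bs.parse_boolnet("targets, factors\nA, 1\nB, 1\n")
        result = bs.solve(net)
        assert result.node_probabilities == pytest.approx({"A": 1.0, "B": 1.0})

    def test_oscillator_single_cyclic_attractor(self, oscillator):
        result = bs.solve(oscillator, rates=bs.TransitionRates.random(oscillator, 3))
        assert len(result.attractors) == 1
        a = result.attractors[0]
        assert a.kind == "cyclic" and a.probability == pytest.approx(1.0)
        assert a.distribution.sum() == pytest.approx(1.0)


class TestSubgraphHandling:
    def test_only_occupied_subgraph_is_solved(self, input_split):
        result = bs.solve(input_split, init={"I": 0})
        assert {a.subgraph for a in result.attractors} == {1}
        assert result.x_star.sum() == pytest.approx(1.0, abs=1e-12)

    def test_occupied_subgraph_matches_full_dense_solve(self, input_split):
        rates = bs.TransitionRates.random(input_split, 11)
        x0 = bs.make_initial_condition(input_split, {"I": 1})
        result = bs.ExactSolver(input_split).solve(rates, x0)
        table = bs.enumerate_transitions(input_split)
        K = bs.build_kinetic_matrix(table, rates, input_split)
        minrate = min(rates.flat().values())
        xt = dense_transient(K, x0, 60.0 / minrate)
        assert np.abs(result.x_star - xt).max() <= 1e-6

    def test_empty_subgraph_attractors_on_request(self, input_split):
        x0 = bs.make_initial_condition(input_split, {"I": 0})
        solver = bs.ExactSolver(input_split)
        rates = bs.TransitionRates.uniform(input_split)
        without = solver.solve(rates, x0)
        with_empty = solver.solve(rates, x0, include_empty=True)
        assert len(with_empty.attractors) == 2 * len(without.attractors)
        empty = [a for a in with_empty.attractors if a.subgraph == 2]
        assert all(a.probability == 0.0 for a in empty)

    def test_knockout_rate_changes_reachability(self, toy3):
        # u_A = 0 removes activation of A; from [000] nothing can move
        rates = bs.TransitionRates.uniform(toy3).replace(u_A=0.0)
        x0 = np.zeros(8)
        x0[0] = 1.0
        result = bs.solve(toy3, rates=rates, init=x0)
        assert result.x_star[0] == pytest.approx(1.0)


class TestResultSerialization:
    def test_json_and_tsv_round_trip(self, toy3):
        import json

        result = bs.solve(toy3)
        doc = json.loads(result.to_json())
        assert doc["nodes"] == ["A", "B", "C"]
        assert len(doc["attractors"]) == 3
        total = sum(a["total_probability"] for a in doc["attractors"])
        assert total == pytest.approx(1.0, abs=1e-9)
        tsv = result.to_tsv()
        assert "fixed_point" in tsv and "node" in tsv
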