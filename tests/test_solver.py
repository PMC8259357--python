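"""Minimum-flip solver: worked examples, oracle agreement, invariants."""

import numpy as np
import pytest

from lppflip import (
    MISSING,
    GenotypeMatrix,
    brute_force_lppf,
    chain_graph_to_matrix,
    compute_z,
    is_linear,
    matrix_to_chain_graph,
    permutation_cost,
    solve_lppf,
    solve_lppf_pattern_encoding,
)

from conftest import random_binary_matrix


def assert_valid_solution(B, sol, z):
    """Solver-independent post-hoc validity check of all solution invariants."""
    F = sol.flipped_matrix
    ok, order = is_linear(GenotypeMatrix(F))
    assert ok, "flipped matrix is not a linear perfect phylogeny"
    # untouched observed entries preserved
    obs = B.entries
    touched = sol.flips_0to1 | sol.flips_1to0 | set(sol.imputed_missing)
    for i in range(B.n):
        for j in range(B.m):
            if (i, j) not in touched:
                assert F[i, j] == obs[i, j]
    assert len(sol.flips_1to0) <= z
    assert sol.objective_y == len(sol.flips_0to1)
    assert all(obs[i, j] == 0 for i, j in sol.flips_0to1)
    assert all(obs[i, j] == 1 for i, j in sol.flips_1to0)
    assert all(obs[i, j] == MISSING for i, j in sol.imputed_missing)


class TestWorkedExamples:
    @pytest.mark.parametrize(
        "rows, z, expected",
        [
            ([[1, 0], [0, 1]], 0, 1),
            ([[1, 1], [0, 1]], 0, 0),
            ([[1, 0], [0, 1], [0, 1]], 0, 1),
            ([[1, 0], [0, 1]], 1, 0),
        ],
    )
    def test_solve_micro(self, rows, z, expected):
        B = GenotypeMatrix(np.array(rows))
        for solver in (solve_lppf, brute_force_lppf):
            sol = solver(B, z=z)
            assert sol.objective_y == expected
            assert sol.status == "OPTIMAL"
            assert_valid_solution(B, sol, z)

    def test_permutation_cost_examples(self, conflict_2x2, linear_2x2):
        # col0 first (most-derived): row (1,0) must fill its trailing zero
        cost, cuts = permutation_cost(conflict_2x2, [0, 1], z=0)
        assert cost == 1
        # optimal order: col0 (one-state {0}) before col1 ({0,1})
        cost, _ = permutation_cost(linear_2x2, [0, 1], z=0)
        assert cost == 0
        for order in ([0, 1], [1, 0]):
            cost, _ = permutation_cost(conflict_2x2, order, z=2)
            assert cost == 0
        with pytest.raises(ValueError):
            permutation_cost(conflict_2x2, [0, 0], z=0)

    def test_error_inputs(self, conflict_2x2):
        with pytest.raises(ValueError):
            solve_lppf(conflict_2x2, z=-1)
        with pytest.raises(ValueError):
            solve_lppf(conflict_2x2, time_limit=0)
        with pytest.raises(ValueError):
            brute_force_lppf(
                GenotypeMatrix(np.zeros((2, 3), dtype=int)), z=0, max_m=2
            )


class TestComputeZ:
    def test_values(self):
        B250 = GenotypeMatrix(np.ones((10, 25), dtype=int))  # 250 ones
        assert compute_z(B250, 0.0) == 0
        assert compute_z(B250, 0.001) == 1  # ceil(0.25)
        assert compute_z(B250, 0.01) == 3  # ceil(2.5)
        with pytest.raises(ValueError):
            compute_z(B250, 1.0)

    def test_missing_excluded(self):
        B = GenotypeMatrix(np.array([[1, MISSING], [1, 1]]))
        # 3 observed ones: ceil(0.3*3)=1; counting MISSING would give ceil(1.2)=2
        assert compute_z(B, 0.3) == 1


class TestOracleAgreement:
    def test_small_random_instances(self):
        rng = np.random.default_rng(515)
        for k in range(80):
            B = random_binary_matrix(rng, n_max=10, m_max=5)
            z = int(rng.integers(0, 3))
            a = solve_lppf(B, z=z, time_limit=30)
            b = brute_force_lppf(B, z=z)
            assert a.objective_y == b.objective_y, (B.entries, z)
            assert_valid_solution(B, a, z)

    def test_pattern_encoding_cross_check(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            B = random_binary_matrix(rng, n_max=8, m_max=4)
            z = int(rng.integers(0, 3))
            assert (
                solve_lppf(B, z=z).objective_y
                == solve_lppf_pattern_encoding(B, z=z).objective_y
            )

    def test_missing_entries_free(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            B = random_binary_matrix(rng, n_max=8, m_max=4, missing_frac=0.2)
            a = solve_lppf(B, z=0)
            b = brute_force_lppf(B, z=0)
            assert a.objective_y == b.objective_y
            assert_valid_solution(B, a, 0)


class TestInvariants:
    def test_monotone_in_z(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            B = random_binary_matrix(rng, n_max=8, m_max=4)
            ys = [solve_lppf(B, z=z).objective_y for z in (0, 1, 2)]
            assert ys[0] >= ys[1] >= ys[2]

    def test_upper_bound_all_zeros(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            B = random_binary_matrix(rng, n_max=8, m_max=4)
            assert solve_lppf(B, z=0).objective_y <= int((B.entries == 0).sum())

    def test_duplicate_column_merge_same_objective(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            base = random_binary_matrix(rng, n_max=8, m_max=3)
            # duplicate a column to create symmetry
            dup = np.hstack([base.entries, base.entries[:, :1]])
            B = GenotypeMatrix(dup)
            assert (
                solve_lppf(B, z=0, merge_duplicate_columns=True).objective_y
                == solve_lppf(B, z=0).objective_y
            )

    def test_determinism(self):
        rng = np.random.default_rng(17)
        B = random_binary_matrix(rng, n_max=10, m_max=5)
        y1 = solve_lppf(B, z=1, seed=1).objective_y
        y2 = solve_lppf(B, z=1, seed=1).objective_y
        assert y1 == y2


class TestChainGraph:
    def test_direct_construction(self, conflict_2x2):
        G = matrix_to_chain_graph(conflict_2x2)
        assert set(G.edges) == {(("cell", 0), ("mut", 0)), (("cell", 1), ("mut", 1))}

    def test_round_trip(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            B = random_binary_matrix(rng, n_max=8, m_max=5)
            assert chain_graph_to_matrix(matrix_to_chain_graph(B)) == GenotypeMatrix(
                B.entries
            )

    def test_chain_graph_matrix_is_linear(self):
        # neighborhoods nested by construction => matrix is linear
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from([("cell", i) for i in range(4)], bipartite=0)
        G.add_nodes_from([("mut", j) for j in range(3)], bipartite=1)
        # eta(mut0) = {0} ⊆ eta(mut1) = {0,1} ⊆ eta(mut2) = {0,1,2,3}
        G.add_edges_from([(("cell", 0), ("mut", 0))])
        G.add_edges_from([(("cell", i), ("mut", 1)) for i in range(2)])
        G.add_edges_from([(("cell", i), ("mut", 2)) for i in range(4)])
        G.graph["n"], G.graph["m"] = 4, 3
        ok, _ = is_linear(chain_graph_to_matrix(G))
        assert ok
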