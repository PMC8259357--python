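"""Clone-tree generator, cell sampling, and the single-cell error model."""

import numpy as np
import pytest

from lppflip import (
    BRANCHED_PATTERN,
    LINEAR_PATTERN,
    CloneTree,
    GenotypeMatrix,
    GridSpec,
    SimulationConfig,
    generate_clone_tree,
    inject_doublets,
    inject_errors,
    is_linear,
    run_robustness_grid,
    sample_cells,
    simulate_instance,
    solve_lppf,
)


class TestCloneTree:
    def test_linear_tree_is_path_and_linear_matrix(self):
        tree = generate_clone_tree(4, LINEAR_PATTERN, seed=0)
        assert tree.parent == [-1, 0, 1, 2, 3]
        B = sample_cells(tree, 50, seed=1)
        ok, _ = is_linear(B)
        assert ok

    def test_branched_tree_has_multifurcation(self):
        for seed in range(10):
            tree = generate_clone_tree(6, BRANCHED_PATTERN, seed=seed)
            children = np.bincount(
                [p for p in tree.parent if p >= 0], minlength=tree.n_clones
            )
            assert (children >= 2).any()

    def test_branched_matrix_fails_linearity_with_cells_on_two_branches(self):
        tree = generate_clone_tree(8, BRANCHED_PATTERN, seed=3)
        G = tree.genotypes()
        children = [
            [c for c in range(tree.n_clones) if tree.parent[c] == p]
            for p in range(tree.n_clones)
        ]
        fork = next(p for p in range(tree.n_clones) if len(children[p]) >= 2)
        a, b = children[fork][:2]
        B = GenotypeMatrix(G[[a, b]].copy())
        ok, _ = is_linear(B)
        assert not ok  # disjoint branch mutations violate containment

    def test_determinism(self):
        t1 = generate_clone_tree(7, BRANCHED_PATTERN, seed=42)
        t2 = generate_clone_tree(7, BRANCHED_PATTERN, seed=42)
        assert t1.parent == t2.parent
        assert np.allclose(t1.prevalences, t2.prevalences)

    def test_branched_needs_two_mutations(self):
        with pytest.raises(ValueError):
            generate_clone_tree(1, BRANCHED_PATTERN, seed=0)

    def test_invalid_tree_rejected(self):
        with pytest.raises(ValueError):
            CloneTree([-1, 0], [[], ["m0"]], [0.6, 0.5], LINEAR_PATTERN)
        with pytest.raises(ValueError):
            CloneTree([-1, 0], [["m0"], ["m0"]], [0.5, 0.5], LINEAR_PATTERN)


class TestSampleCells:
    def test_rows_match_clone_genotypes(self):
        tree = generate_clone_tree(6, BRANCHED_PATTERN, seed=5)
        B = sample_cells(tree, 200, seed=6)
        G = tree.genotypes()
        assert np.array_equal(B.entries, G[B.cell_clones])

    def test_single_clone_tree(self):
        tree = CloneTree([-1, 0], [[], ["mut0"]], [0.0, 1.0], LINEAR_PATTERN)
        B = sample_cells(tree, 10, seed=0)
        assert (B.entries == 1).all()

    def test_prevalence_concentration(self):
        tree = CloneTree(
            [-1, 0], [[], ["mut0"]], [0.5, 0.5], LINEAR_PATTERN
        )
        B = sample_cells(tree, 10_000, seed=9)
        frac = (B.cell_clones == 0).mean()
        assert abs(frac - 0.5) < 0.02


class TestInjectErrors:
    def test_zero_rates_identity(self):
        tree = generate_clone_tree(5, LINEAR_PATTERN, seed=0)
        B = sample_cells(tree, 30, seed=0)
        out, fns, fps = inject_errors(B, 0.0, 0.0, seed=1)
        assert np.array_equal(out.entries, B.entries)
        assert fns == fps == set()

    def test_fn_count_within_binomial_bounds(self):
        entries = np.ones((100, 10), dtype=np.int8)  # 1000 ones
        B = GenotypeMatrix(entries)
        beta = 0.15
        out, fns, _ = inject_errors(B, beta, 0.0, seed=2)
        sigma = np.sqrt(1000 * beta * (1 - beta))
        assert abs(len(fns) - 150) < 3 * sigma
        assert (out.entries == 0).sum() == len(fns)

    def test_determinism(self):
        B = GenotypeMatrix(np.ones((20, 5), dtype=np.int8))
        a = inject_errors(B, 0.2, 0.0, seed=7)[0]
        b = inject_errors(B, 0.2, 0.0, seed=7)[0]
        assert np.array_equal(a.entries, b.entries)


class TestInjectDoublets:
    def test_zero_delta_identity(self):
        B = GenotypeMatrix(np.eye(4, dtype=np.int8))
        out, hit = inject_doublets(B, 0.0, seed=0)
        assert np.array_equal(out.entries, B.entries) and hit == set()

    def test_nested_genotypes_merge_to_derived(self):
        # along a path, OR of two nested genotypes equals the more derived
        tree = generate_clone_tree(5, LINEAR_PATTERN, seed=0)
        G = tree.genotypes()
        merged = np.maximum(G[2], G[4])
        assert np.array_equal(merged, G[4])

    def test_cross_branch_doublet_unions_branches(self):
        rows = np.array([[1, 0], [0, 1]], dtype=np.int8)  # two branches
        B = GenotypeMatrix(rows)
        out, hit = inject_doublets(B, 0.999, seed=12)
        for i in hit:
            assert (out.entries[i] >= rows[i]).all()
        # at least one merged row contains both branch mutations
        assert any((out.entries[i] == 1).all() for i in hit) or len(hit) == 0


class TestGridPipeline:
    def test_error_free_linear_grid_all_zero_flips(self):
        spec = GridSpec(
            n=60, m_values=(5,), beta_values=(0.0,), alpha_values=(0.0,),
            delta_values=(0.0,), patterns=(LINEAR_PATTERN,), replicates=2,
            time_limit=30, seed=1,
        )
        from lppflip import HypothesisParams

        res = run_robustness_grid(
            spec, branched_priors={5: HypothesisParams(0.15, 10)}
        )
        assert (res["y"] == 0).all()
        assert (res["label"] == "LINEAR").all()

    def test_repair_bound_fn_only(self):
        # with only false negatives injected, the solver never needs more
        # flips than were injected
        for seed in range(5):
            tree = generate_clone_tree(6, LINEAR_PATTERN, seed=seed)
            B_true = sample_cells(tree, 80, seed=seed)
            noisy, fns, _ = inject_errors(B_true, 0.2, 0.0, seed=seed + 100)
            sol = solve_lppf(noisy, z=0, time_limit=60)
            assert sol.objective_y <= len(fns)

    def test_instance_reproducibility(self):
        cfg = SimulationConfig(n=40, m=8, pattern=BRANCHED_PATTERN,
                               beta=0.1, alpha=0.01, delta=0.1, seed=77)
        _, a_true, a_obs = simulate_instance(cfg, replicate=1)
        _, b_true, b_obs = simulate_instance(cfg, replicate=1)
        assert np.array_equal(a_obs.entries, b_obs.entries)
        _, _, c_obs = simulate_instance(cfg, replicate=2)
        assert not np.array_equal(a_obs.entries, c_obs.entries)
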