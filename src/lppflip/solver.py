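"""Exact minimum-flip solver for the linear perfect phylogeny flipping problem.

Given an observed genotype matrix B and a budget ``z`` of allowed 1→0 flips
(expected false positives), find the minimum number of 0→1 flips (inferred
false negatives) so that the flipped matrix B′ is a linear perfect
phylogeny.  The problem is NP-hard (equivalent to chain-graph edge
insertion), so the solver uses an exact mixed-integer program:

* ``x_ij ∈ {0,1}`` is the flipped matrix B′;
* for every unordered column pair ``{a, b}`` a boolean ``w_ab`` selects
  which containment holds: ``w_ab = 1`` forces ``x_·a ≤ x_·b`` row-wise
  (one-state of a ⊆ one-state of b), ``w_ab = 0`` forces the reverse.

Pairwise ⊆-comparability of all one-states is equivalent to the existence
of a total ⊆-order (a family of pairwise nested sets is a chain), so the
column-permutation variables of the textbook constraint-program formulation
are not needed explicitly; the permutation is read off the solved B′.  The
objective charges each observed 0 that ends up 1; a single knapsack row
caps the observed 1s that end up 0 at ``z``.  MISSING entries are free
variables with zero cost that count toward neither flip set.

In practice the LP relaxation of this model is almost always integral at a
vertex, so the solver first runs an interior-point LP: an integral
LP-optimal solution attains the LP lower bound and is returned as a proven
integer optimum.  Only fractional cases fall through to branch and bound
(with a greedy feasible solution as an objective cut).

A brute-force oracle (all column permutations × per-row cut positions with
a shared 1→0 budget) and an alternative encoding that directly forbids the
2×2 ``[[1,0],[0,1]]`` submatrix are provided for cross-validation.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass
from itertools import permutations

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .matrix import MISSING, GenotypeMatrix, is_linear

# -- solution container -----------------------------------------------------

OPTIMAL = "OPTIMAL"
FEASIBLE_TIMEOUT = "FEASIBLE_TIMEOUT"
INFEASIBLE = "INFEASIBLE"  # never returned for valid input; kept for status vocabulary


@dataclass
class LppfSolution:
    """Result of a minimum-flip computation.

    ``order`` lists column indices from most-derived (smallest one-state in
    the flipped matrix) to root-adjacent (largest).  ``flips_0to1`` is the
    set F whose size is the objective y; ``flips_1to0`` respects the z cap;
    ``imputed_missing`` maps MISSING positions to their assigned value.
    """

    flipped_matrix: np.ndarray
    order: list[int]
    flips_0to1: set[tuple[int, int]]
    flips_1to0: set[tuple[int, int]]
    imputed_missing: dict[tuple[int, int], int]
    objective_y: int
    status: str
    z: int = 0
    seed: int | None = None
    runtime_s: float = 0.0

    def to_dict(self, B: GenotypeMatrix) -> dict:
        """JSON-ready record with user-facing labels (most-derived first)."""
        cl, ml = B.cell_labels, B.mutation_labels
        return {
            "objective": self.objective_y,
            "status": self.status,
            "order": [ml[j] for j in self.order],
            "flips_0to1": sorted((cl[i], ml[j]) for i, j in self.flips_0to1),
            "flips_1to0": sorted((cl[i], ml[j]) for i, j in self.flips_1to0),
            "imputed_missing": sorted(
                (cl[i], ml[j], int(v)) for (i, j), v in self.imputed_missing.items()
            ),
            "z": self.z,
            "seed": self.seed,
            "runtime_s": round(self.runtime_s, 3),
        }


def compute_z(B: GenotypeMatrix, alpha: float, count_missing: bool = False) -> int:
    """Expected false-positive budget ``z = ⌈α · (#1-entries of B)⌉``.

    MISSING entries are excluded from the ones-count by default
    (``count_missing=True`` treats them as potential ones instead).
    """
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    ones = B.ones_count()
    if count_missing:
        ones += int((B.entries == MISSING).sum())
    return math.ceil(alpha * ones)


# -- fixed-permutation cost (oracle building block) -------------------------

def permutation_cost(
    B: GenotypeMatrix, order: list[int], z: int = 0
) -> tuple[int, list[int]]:
    """Minimum 0→1 flips to linearize ``B`` under a fixed column order.

    With the columns arranged most-derived first, every row of a linear
    perfect phylogeny reads as zeros followed by ones.  Each row therefore
    chooses a cut position ``t``: columns ``order[:t]`` become 0 and
    ``order[t:]`` become 1.  Per-row cut costs are independent except for
    the shared 1→0 budget ``z``, which a small dynamic program over the
    budget resolves exactly.

    Returns ``(total 0→1 cost, cut position per row)``.  A cut at 0 (all
    ones) incurs no 1→0 cost, so a feasible choice always exists.
    """
    m = B.m
    if sorted(order) != list(range(m)):
        raise ValueError("order is not a permutation of the columns")
    sub = B.entries[:, order]
    n = B.n
    # c01[i, t] / c10[i, t]: costs of cutting row i at t (t in 0..m)
    isone = (sub == 1).astype(np.int64)
    iszero = (sub == 0).astype(np.int64)
    zeros_suffix = np.hstack(
        [np.cumsum(iszero[:, ::-1], axis=1)[:, ::-1], np.zeros((n, 1), dtype=np.int64)]
    )
    ones_prefix = np.hstack([np.zeros((n, 1), dtype=np.int64), np.cumsum(isone, axis=1)])
    c01 = zeros_suffix  # zeros at or after the cut must flip to 1
    c10 = ones_prefix  # ones before the cut must flip to 0
    z = int(z)
    INF = np.iinfo(np.int64).max // 4
    # dp[b] = min total 0→1 cost using exactly ≤ b of the 1→0 budget
    dp = np.zeros(z + 1, dtype=np.int64)
    choice = np.zeros((n, z + 1), dtype=np.int64)
    for i in range(n):
        ndp = np.full(z + 1, INF, dtype=np.int64)
        pick = np.zeros(z + 1, dtype=np.int64)
        for t in range(m + 1):
            cost10 = c10[i, t]
            if cost10 > z:
                continue
            cand = np.full(z + 1, INF, dtype=np.int64)
            cand[cost10:] = dp[: z + 1 - cost10] + c01[i, t]
            better = cand < ndp
            ndp = np.where(better, cand, ndp)
            pick = np.where(better, t, pick)
        # dp stays monotone non-increasing in b (inherited from the previous
        # row), so ndp is already the budget-b optimum
        dp = ndp
        choice[i] = pick
    best_b = int(np.argmin(dp))  # first (smallest-budget) optimum
    total = int(dp[best_b])
    # reconstruct cuts backwards
    cuts = [0] * n
    b = best_b
    for i in range(n - 1, -1, -1):
        t = int(choice[i, b])
        cuts[i] = t
        b -= int(c10[i, t])
    return total, cuts


def _solution_from_cuts(
    B: GenotypeMatrix, order: list[int], cuts: list[int], z: int
) -> LppfSolution:
    n, m = B.n, B.m
    flipped = np.zeros((n, m), dtype=np.int8)
    for i, t in enumerate(cuts):
        flipped[i, order[t:]] = 1
    return _finalize_solution(B, flipped, z=z, status=OPTIMAL, seed=None, runtime=0.0)


def brute_force_lppf(B: GenotypeMatrix, z: int = 0, max_m: int = 8) -> LppfSolution:
    """Exact minimum-flip solution by enumerating all m! column orders.

    Test oracle: independent of the mixed-integer path.  Guarded at
    ``m ≤ max_m`` (factorial blow-up).
    """
    if B.m > max_m:
        raise ValueError(f"brute force guarded at m <= {max_m}, got m={B.m}")
    if z < 0:
        raise ValueError("z must be non-negative")
    best: tuple[int, list[int], list[int]] | None = None
    for order in permutations(range(B.m)):
        cost, cuts = permutation_cost(B, list(order), z)
        if best is None or cost < best[0]:
            best = (cost, list(order), cuts)
    assert best is not None
    return _solution_from_cuts(B, best[1], best[2], z)


# -- chain-graph conversions ------------------------------------------------

def matrix_to_chain_graph(B: GenotypeMatrix) -> nx.Graph:
    """Bipartite graph with an edge (cell i, mutation v) iff ``b_iv = 1``.

    ``B`` is a linear perfect phylogeny exactly when the graph is a chain
    graph (right-side neighborhoods nested under inclusion).
    """
    if not B.is_complete:
        raise ValueError("chain-graph conversion requires a complete binary matrix")
    G = nx.Graph()
    cells = [("cell", i) for i in range(B.n)]
    muts = [("mut", j) for j in range(B.m)]
    G.add_nodes_from(cells, bipartite=0)
    G.add_nodes_from(muts, bipartite=1)
    rows, cols = np.nonzero(B.entries == 1)
    G.add_edges_from((("cell", int(i)), ("mut", int(j))) for i, j in zip(rows, cols))
    G.graph["n"] = B.n
    G.graph["m"] = B.m
    return G


def chain_graph_to_matrix(G: nx.Graph) -> GenotypeMatrix:
    """Inverse of :func:`matrix_to_chain_graph`."""
    cells = sorted(v for v in G.nodes if v[0] == "cell")
    muts = sorted(v for v in G.nodes if v[0] == "mut")
    n = G.graph.get("n", len(cells))
    m = G.graph.get("m", len(muts))
    entries = np.zeros((n, m), dtype=np.int8)
    for u, v in G.edges:
        if u[0] == "mut":
            u, v = v, u
        entries[u[1], v[1]] = 1
    return GenotypeMatrix(entries)


# -- exact mixed-integer solver ---------------------------------------------

def _finalize_solution(
    B: GenotypeMatrix,
    flipped: np.ndarray,
    z: int,
    status: str,
    seed: int | None,
    runtime: float,
) -> LppfSolution:
    obs = B.entries
    f01 = {(int(i), int(j)) for i, j in zip(*np.nonzero((obs == 0) & (flipped == 1)))}
    f10 = {(int(i), int(j)) for i, j in zip(*np.nonzero((obs == 1) & (flipped == 0)))}
    imputed = {
        (int(i), int(j)): int(flipped[i, j])
        for i, j in zip(*np.nonzero(obs == MISSING))
    }
    ok, order = is_linear(GenotypeMatrix(flipped))
    if not ok:  # pragma: no cover - solver contract violation
        raise RuntimeError("internal error: solver returned a non-linear matrix")
    return LppfSolution(
        flipped_matrix=flipped,
        order=order,
        flips_0to1=f01,
        flips_1to0=f10,
        imputed_missing=imputed,
        objective_y=len(f01),
        status=status,
        z=z,
        seed=seed,
        runtime_s=runtime,
    )


def solve_lppf(
    B: GenotypeMatrix,
    z: int = 0,
    time_limit: float = 500.0,
    seed: int | None = None,
    merge_duplicate_columns: bool = False,
    _col_weights: np.ndarray | None = None,
) -> LppfSolution:
    """Minimum 0→1 flips making ``B`` a linear perfect phylogeny, ≤ ``z`` 1→0 flips.

    Returns a proven-optimal solution (``status=OPTIMAL``) or, if
    ``time_limit`` seconds elapse first, the best incumbent
    (``status=FEASIBLE_TIMEOUT``).  A feasible solution always exists
    (flip everything to 1), so the call never fails for valid input.

    MISSING entries may take either value at zero cost; they are excluded
    from both flip sets and reported via ``imputed_missing``.  Duplicate
    rows are merged internally with multiplicities when ``z = 0`` (the
    reduction is exact only then — a shared 1→0 budget may be spent
    asymmetrically across identical rows).  ``merge_duplicate_columns``
    additionally collapses observed-identical columns (same z = 0
    restriction), solving once and duplicating the result back.
    """
    if z < 0:
        raise ValueError("z must be non-negative")
    if time_limit <= 0:
        raise ValueError("time_limit must be positive")
    t0 = time.monotonic()

    # optional symmetry reduction: observed-identical columns can share one
    # solved column (exact at z = 0 only, for the same budget-splitting
    # reason as row merging)
    if merge_duplicate_columns and z == 0 and B.m > 1:
        _, first_idx = np.unique(B.entries, axis=1, return_index=True)
        if first_idx.size < B.m:
            keep = np.sort(first_idx)
            # flip cost in a merged column applies to every duplicate
            mult = np.array(
                [
                    sum(
                        np.array_equal(B.entries[:, j], B.entries[:, rep])
                        for j in range(B.m)
                    )
                    for rep in keep
                ],
                dtype=float,
            )
            reduced = GenotypeMatrix(B.entries[:, keep])
            sub = solve_lppf(
                reduced, z=0, time_limit=time_limit, seed=seed, _col_weights=mult
            )
            # duplicate each representative's solved column back
            expanded = np.empty((B.n, B.m), dtype=np.int8)
            for j in range(B.m):
                k = next(
                    k for k, rep in enumerate(keep)
                    if np.array_equal(B.entries[:, j], B.entries[:, rep])
                )
                expanded[:, j] = sub.flipped_matrix[:, k]
            return _finalize_solution(
                B, expanded, z, sub.status, seed, time.monotonic() - t0
            )
    elif merge_duplicate_columns and z > 0:
        warnings.warn(
            "merge_duplicate_columns is exact only at z = 0; ignoring",
            stacklevel=2,
        )

    # fast path: an already-linear complete matrix needs no flips
    if B.is_complete:
        ok, order = is_linear(B)
        if ok:
            return LppfSolution(
                flipped_matrix=B.entries.copy(),
                order=order,
                flips_0to1=set(),
                flips_1to0=set(),
                imputed_missing={},
                objective_y=0,
                status=OPTIMAL,
                z=z,
                seed=seed,
                runtime_s=time.monotonic() - t0,
            )

    # Merge duplicate rows. Exact only when z = 0: for a fixed column order
    # each row is then optimized independently, so identical rows may share
    # one variable block. With z > 0 an optimum may spend the shared 1→0
    # budget asymmetrically across identical rows, so no merging is done.
    if z == 0:
        uniq, inverse, weights = np.unique(
            B.entries, axis=0, return_inverse=True, return_counts=True
        )
    else:
        uniq = B.entries
        inverse = np.arange(B.n)
        weights = np.ones(B.n, dtype=np.int64)
    R, m = uniq.shape
    npairs = m * (m - 1) // 2
    nx_vars = R * m
    nvars = nx_vars + npairs

    def xv(r: int, j: int) -> int:
        return r * m + j

    pair_index = {}
    k = nx_vars
    for a in range(m):
        for b in range(a + 1, m):
            pair_index[(a, b)] = k
            k += 1

    c = np.zeros(nvars)
    lb = np.zeros(nvars)
    ub = np.ones(nvars)
    w = weights.astype(float)
    colw = np.ones(m) if _col_weights is None else np.asarray(_col_weights, float)
    for r in range(R):
        row = uniq[r]
        zero_j = np.nonzero(row == 0)[0]
        c[[xv(r, j) for j in zero_j]] = w[r] * colw[zero_j]
    if z == 0:
        # observed ones cannot flip: fix x = 1
        for r in range(R):
            for j in np.nonzero(uniq[r] == 1)[0]:
                lb[xv(r, j)] = 1.0

    # greedy feasible solution: order columns by observed one-state size,
    # then per-row optimal cuts.  Used for an early exit when already
    # optimal (cost 0), as an objective cut in the integer fallback, and as
    # a guaranteed answer if the search times out with no incumbent.
    sizes = (B.entries == 1).sum(axis=0)
    greedy_order = [int(j) for j in np.argsort(sizes, kind="stable")]
    ub_cost, ub_cuts = permutation_cost(B, greedy_order, z)
    if ub_cost == 0:
        sol = _solution_from_cuts(B, greedy_order, ub_cuts, z)
        sol.seed = seed
        sol.runtime_s = time.monotonic() - t0
        return sol

    # pairwise comparability constraints:
    #   x_ra - x_rb + w_ab <= 1   (w_ab = 1 ⇒ column a ⊆ column b)
    #   x_rb - x_ra - w_ab <= 0   (w_ab = 0 ⇒ column b ⊆ column a)
    rows_i: list[int] = []
    cols_i: list[int] = []
    vals: list[float] = []
    con_ub: list[float] = []
    cr = 0
    for (a, b), wk in pair_index.items():
        for r in range(R):
            if z == 0 and uniq[r, a] == uniq[r, b] == 1:
                continue  # both fixed to 1: constraints vacuous
            xa, xb = xv(r, a), xv(r, b)
            rows_i += [cr, cr, cr]
            cols_i += [xa, xb, wk]
            vals += [1.0, -1.0, 1.0]
            con_ub.append(1.0)
            cr += 1
            rows_i += [cr, cr, cr]
            cols_i += [xa, xb, wk]
            vals += [-1.0, 1.0, -1.0]
            con_ub.append(0.0)
            cr += 1
    A_pairs = None
    if cr:
        A_pairs = sparse.coo_matrix(
            (vals, (rows_i, cols_i)), shape=(cr, nvars)
        ).tocsr()
    A_knap = None
    knap_lb = 0.0
    if z > 0:
        # Σ weight·(1 - x) over observed ones ≤ z
        data, idx = [], []
        total_ones = 0.0
        for r in range(R):
            for j in np.nonzero(uniq[r] == 1)[0]:
                idx.append(xv(r, j))
                data.append(w[r])
                total_ones += w[r]
        if idx:
            A_knap = sparse.coo_matrix(
                (data, (np.zeros(len(idx), dtype=int), idx)), shape=(1, nvars)
            ).tocsr()
            knap_lb = total_ones - z

    # Phase 1: LP relaxation by interior point.  For this model the
    # relaxation is very often integral at a vertex; an integral LP-optimal
    # solution attains the LP lower bound and is therefore a proven integer
    # optimum.  Dual simplex (the branch-and-bound workhorse) is an order of
    # magnitude slower on these large degenerate LPs, so this phase usually
    # replaces the integer search entirely.
    remaining = time_limit - (time.monotonic() - t0)
    blocks, rhs = [], []
    if A_pairs is not None:
        blocks.append(A_pairs)
        rhs.append(np.asarray(con_ub))
    if A_knap is not None:
        blocks.append(-A_knap)
        rhs.append(np.array([-knap_lb]))
    lp = linprog(
        c,
        A_ub=sparse.vstack(blocks).tocsr() if blocks else None,
        b_ub=np.concatenate(rhs) if rhs else None,
        bounds=np.column_stack([lb, ub]),
        method="highs-ipm",
        options={"time_limit": max(remaining, 1.0)},
    )
    if lp.status == 0 and lp.x is not None:
        xr = np.asarray(lp.x)
        if np.max(np.abs(xr - np.round(xr))) < 1e-6:
            xint = np.round(xr[:nx_vars]).reshape(R, m) > 0.5
            flipped = xint[inverse].astype(np.int8)
            y_int = int(round(float(c[:nx_vars] @ np.round(xr[:nx_vars]))))
            if y_int == int(round(lp.fun)):
                try:
                    sol = _finalize_solution(
                        B, flipped, z, OPTIMAL, seed, time.monotonic() - t0
                    )
                    weighted_y = int(round(sum(colw[j] for _, j in sol.flips_0to1)))
                    if len(sol.flips_1to0) <= z and weighted_y == y_int:
                        return sol
                except RuntimeError:  # pragma: no cover - fall through to MIP
                    pass

    # Phase 2: exact integer search (fractional relaxation or LP failure)
    constraints = []
    if A_pairs is not None:
        constraints.append(LinearConstraint(A_pairs, -np.inf, np.asarray(con_ub)))
    if A_knap is not None:
        constraints.append(LinearConstraint(A_knap, knap_lb, np.inf))
    nz = np.nonzero(c)[0]
    if nz.size and _col_weights is None:
        # greedy bound is an unweighted flip count, comparable to c only
        # when all column weights are 1
        Aub = sparse.coo_matrix(
            (c[nz], (np.zeros(nz.size, dtype=int), nz)), shape=(1, nvars)
        ).tocsr()
        constraints.append(LinearConstraint(Aub, -np.inf, float(ub_cost)))

    remaining = time_limit - (time.monotonic() - t0)
    if remaining <= 0.5:
        sol = _solution_from_cuts(B, greedy_order, ub_cuts, z)
        sol.status = FEASIBLE_TIMEOUT
        sol.seed = seed
        sol.runtime_s = time.monotonic() - t0
        return sol
    res = milp(
        c,
        constraints=constraints,
        integrality=np.ones(nvars),
        bounds=Bounds(lb, ub),
        options={"time_limit": max(remaining, 1.0)},
    )
    runtime = time.monotonic() - t0
    if res.status == 0:
        status = OPTIMAL
    elif res.status == 1 and res.x is not None:
        status = FEASIBLE_TIMEOUT
    elif res.x is None:
        # no incumbent from the search: fall back to the greedy solution
        sol = _solution_from_cuts(B, greedy_order, ub_cuts, z)
        sol.status = FEASIBLE_TIMEOUT
        sol.seed = seed
        sol.runtime_s = runtime
        return sol
    else:  # pragma: no cover - unexpected solver state
        raise RuntimeError(f"MILP solver failed: {res.message}")
    xsol = np.asarray(res.x[:nx_vars]).reshape(R, m) > 0.5
    flipped = xsol[inverse].astype(np.int8)
    return _finalize_solution(B, flipped, z, status, seed, runtime)


def solve_lppf_pattern_encoding(
    B: GenotypeMatrix, z: int = 0, time_limit: float = 60.0
) -> LppfSolution:
    """Alternative exact encoding forbidding the 2×2 ``[[1,0],[0,1]]`` submatrix.

    A binary matrix is a linear perfect phylogeny iff no pair of rows and
    pair of columns induces that pattern (the forbidden-submatrix
    characterization of chain graphs).  O(n²m²) constraints, so intended
    for cross-checking the primary encoding on small inputs only.
    """
    if z < 0:
        raise ValueError("z must be non-negative")
    if z == 0:
        uniq, inverse, weights = np.unique(
            B.entries, axis=0, return_inverse=True, return_counts=True
        )
    else:
        uniq = B.entries
        inverse = np.arange(B.n)
        weights = np.ones(B.n, dtype=np.int64)
    R, m = uniq.shape
    nvars = R * m

    def xv(r: int, j: int) -> int:
        return r * m + j

    c = np.zeros(nvars)
    for r in range(R):
        for j in np.nonzero(uniq[r] == 0)[0]:
            c[xv(r, j)] = weights[r]
    rows_i: list[int] = []
    cols_i: list[int] = []
    vals: list[float] = []
    cr = 0
    for p in range(R):
        for q in range(p + 1, R):
            for a in range(m):
                for b in range(a + 1, m):
                    for (r1, r2) in ((p, q), (q, p)):
                        # x[r1,a] + x[r2,b] - x[r1,b] - x[r2,a] <= 1
                        rows_i += [cr] * 4
                        cols_i += [xv(r1, a), xv(r2, b), xv(r1, b), xv(r2, a)]
                        vals += [1.0, 1.0, -1.0, -1.0]
                        cr += 1
    constraints = []
    if cr:
        A = sparse.coo_matrix((vals, (rows_i, cols_i)), shape=(cr, nvars)).tocsr()
        constraints.append(LinearConstraint(A, -np.inf, np.ones(cr)))
    lb = np.zeros(nvars)
    if z == 0:
        for r in range(R):
            for j in np.nonzero(uniq[r] == 1)[0]:
                lb[xv(r, j)] = 1.0
    else:
        data, idx = [], []
        total_ones = 0.0
        for r in range(R):
            for j in np.nonzero(uniq[r] == 1)[0]:
                idx.append(xv(r, j))
                data.append(float(weights[r]))
                total_ones += weights[r]
        if idx:
            Az = sparse.coo_matrix(
                (data, (np.zeros(len(idx), dtype=int), idx)), shape=(1, nvars)
            ).tocsr()
            constraints.append(LinearConstraint(Az, total_ones - z, np.inf))
    res = milp(
        c,
        constraints=constraints,
        integrality=np.ones(nvars),
        bounds=Bounds(lb, np.ones(nvars)),
        options={"time_limit": time_limit},
    )
    if res.status != 0 or res.x is None:
        raise RuntimeError(f"cross-check MILP did not solve to optimality: {res.message}")
    xsol = np.asarray(res.x).reshape(R, m) > 0.5
    flipped = xsol[inverse].astype(np.int8)
    return _finalize_solution(B, flipped, z, OPTIMAL, None, 0.0)
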