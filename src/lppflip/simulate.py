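"""Clone-tree simulator, single-cell error model, and the robustness grid.

Ground truth is a rooted clonal tree: clone 0 is the mutation-free founder
and each subsequent clone adds exactly one new mutation on its incoming
edge (infinite sites).  A LINEAR tree is a path — the signature of linear
evolution — while a BRANCHED tree is a random-attachment tree forced to
contain at least one multifurcation with sampled descendants on distinct
branches.  Cells are drawn per clonal prevalence, then corrupted with the
three characteristic single-cell artifacts:

* doublets (probability δ): a cell's row is OR-merged with the true
  genotype of a second, uniformly chosen cell — two cells co-captured and
  sequenced once (applied before read errors, since the merged material is
  what gets sequenced);
* false negatives (probability β per true 1): allelic dropout;
* false positives (probability α per true 0).

The robustness grid sweeps (m, β, α, δ, pattern), solves every instance
with the false-positive budget z = ⌈α·#ones⌉, and classifies it by Bayes
factor with a branched prior fitted per m from an independent
branched-only calibration run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hypothesis import (
    DEFAULT_BRANCHED_PRIOR,
    DEFAULT_LINEAR_PRIOR,
    HypothesisParams,
    classify_solution,
    fit_branched_prior,
)
from .matrix import GenotypeMatrix
from .solver import compute_z, solve_lppf

LINEAR_PATTERN = "LINEAR"
BRANCHED_PATTERN = "BRANCHED"


@dataclass
class CloneTree:
    """Rooted clonal tree with one mutation per edge and clonal prevalences.

    ``parent[c]`` is the parent clone of clone ``c`` (−1 for the root,
    clone 0); the edge into clone ``c`` carries ``edge_mutations[c]``.
    A clone's genotype is the union of mutations on its root path.
    """

    parent: list[int]
    edge_mutations: list[list[str]]
    prevalences: np.ndarray
    pattern: str

    def __post_init__(self) -> None:
        self.prevalences = np.asarray(self.prevalences, dtype=float)
        k = len(self.parent)
        if len(self.edge_mutations) != k or self.prevalences.shape != (k,):
            raise ValueError("parent, edge_mutations and prevalences disagree on size")
        if np.any(self.prevalences < 0) or abs(self.prevalences.sum() - 1) > 1e-9:
            raise ValueError("prevalences must be non-negative and sum to 1")
        seen: set[str] = set()
        for muts in self.edge_mutations:
            for x in muts:
                if x in seen:
                    raise ValueError(f"mutation {x!r} labels more than one edge")
                seen.add(x)
        is_path = all(
            sum(1 for p in self.parent if p == c) <= 1 for c in range(k)
        )
        if (self.pattern == LINEAR_PATTERN) != is_path:
            raise ValueError(f"pattern {self.pattern} inconsistent with topology")

    @property
    def n_clones(self) -> int:
        return len(self.parent)

    @property
    def mutation_labels(self) -> list[str]:
        return [x for muts in self.edge_mutations for x in muts]

    def genotypes(self) -> np.ndarray:
        """(n_clones, m) binary matrix of true clone genotypes."""
        labels = self.mutation_labels
        col = {x: j for j, x in enumerate(labels)}
        G = np.zeros((self.n_clones, len(labels)), dtype=np.int8)
        for c in range(self.n_clones):
            node = c
            while node > 0:
                for x in self.edge_mutations[node]:
                    G[c, col[x]] = 1
                node = self.parent[node]
        return G


@dataclass
class SimulationConfig:
    """One cell of the simulation design."""

    n: int = 500
    m: int = 25
    pattern: str = BRANCHED_PATTERN
    beta: float = 0.0
    alpha: float = 0.0
    delta: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("beta", "alpha", "delta"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.n < 1 or self.m < 1 or self.replicates < 1:
            raise ValueError("n, m and replicates must be >= 1")


def generate_clone_tree(
    m: int,
    pattern: str,
    seed: int,
    branch_factor: float | None = None,
    prevalences: Sequence[float] | None = None,
) -> CloneTree:
    """Random clone tree with ``m`` mutations, one per edge (``m+1`` clones).

    LINEAR builds the path 0→1→…→m.  BRANCHED attaches each new clone to a
    uniformly chosen existing clone and rejection-samples until some clone
    has at least two children.  Prevalences default to a symmetric
    Dirichlet(1) draw over all clones.  Deterministic under ``seed``.
    """
    if m < 2 and pattern == BRANCHED_PATTERN:
        raise ValueError("a branched tree needs at least 2 mutations")
    if m < 1:
        raise ValueError("m must be >= 1")
    if pattern not in (LINEAR_PATTERN, BRANCHED_PATTERN):
        raise ValueError(f"unknown pattern {pattern!r}")
    rng = np.random.default_rng(seed)
    if pattern == LINEAR_PATTERN:
        parent = [-1] + list(range(m))
    else:
        while True:
            parent = [-1]
            for c in range(1, m + 1):
                parent.append(int(rng.integers(0, c)))
            children = np.bincount([p for p in parent if p >= 0], minlength=m + 1)
            if (children >= 2).any():
                break
    edge_mutations = [[]] + [[f"mut{j}"] for j in range(m)]
    if prevalences is None:
        prev = rng.dirichlet(np.ones(m + 1))
    else:
        prev = np.asarray(prevalences, dtype=float)
    return CloneTree(parent, edge_mutations, prev, pattern)


def sample_cells(tree: CloneTree, n: int, seed: int) -> GenotypeMatrix:
    """Error-free matrix B*: each row is a clone genotype drawn by prevalence.

    The drawn clone index per cell is kept as ``cell_clones`` metadata for
    downstream accuracy / AD-distance evaluation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if tree.prevalences.size == 0:
        raise ValueError("tree has no clones")
    rng = np.random.default_rng(seed)
    clones = rng.choice(tree.n_clones, size=n, p=tree.prevalences)
    G = tree.genotypes()
    return GenotypeMatrix(
        G[clones].copy(),
        mutation_labels=tree.mutation_labels,
        cell_clones=clones,
    )


def inject_errors(
    B: GenotypeMatrix, beta: float, alpha: float, seed: int
) -> tuple[GenotypeMatrix, set[tuple[int, int]], set[tuple[int, int]]]:
    """Flip each true 1 to 0 w.p. ``beta`` and each true 0 to 1 w.p. ``alpha``.

    Returns ``(noisy matrix, false-negative positions, false-positive
    positions)``; the recorded positions drive the repair-bound checks.
    """
    for name, v in (("beta", beta), ("alpha", alpha)):
        if not 0 <= v < 1:
            raise ValueError(f"{name} must be in [0, 1), got {v}")
    rng = np.random.default_rng(seed)
    E = B.entries.copy()
    u = rng.random(E.shape)
    fn_mask = (B.entries == 1) & (u < beta)
    fp_mask = (B.entries == 0) & (u < alpha)
    E[fn_mask] = 0
    E[fp_mask] = 1
    fns = {(int(i), int(j)) for i, j in zip(*np.nonzero(fn_mask))}
    fps = {(int(i), int(j)) for i, j in zip(*np.nonzero(fp_mask))}
    out = GenotypeMatrix(
        E, list(B.cell_labels), list(B.mutation_labels), B.cell_clones
    )
    return out, fns, fps


def inject_doublets(
    B: GenotypeMatrix, delta: float, seed: int
) -> tuple[GenotypeMatrix, set[int]]:
    """With probability ``delta`` per cell, OR-merge its row with the true
    genotype of a second cell chosen uniformly among the sampled cells.

    Applied to the error-free matrix (a doublet is co-captured material
    that is then sequenced once, so read errors come afterwards).  Returns
    the merged matrix and the affected row indices.
    """
    if not 0 <= delta < 1:
        raise ValueError(f"delta must be in [0, 1), got {delta}")
    rng = np.random.default_rng(seed)
    E = B.entries.copy()
    hit = np.flatnonzero(rng.random(B.n) < delta)
    partners = rng.integers(0, B.n, size=hit.size)
    for i, p in zip(hit, partners):
        E[i] = np.maximum(E[i], B.entries[p])
    out = GenotypeMatrix(
        E, list(B.cell_labels), list(B.mutation_labels), B.cell_clones
    )
    return out, {int(i) for i in hit}


def simulate_instance(
    config: SimulationConfig, replicate: int = 0
) -> tuple[CloneTree, GenotypeMatrix, GenotypeMatrix]:
    """One seeded instance: returns (tree, error-free B*, observed B)."""
    # stable across processes (never use hash(): it is salted per run)
    pattern_code = 0 if config.pattern == LINEAR_PATTERN else 1
    base = np.random.default_rng(
        [config.seed, replicate, config.m, pattern_code]
    )
    s_tree, s_cells, s_doub, s_err = base.integers(0, 2**31, size=4)
    tree = generate_clone_tree(config.m, config.pattern, int(s_tree))
    B_true = sample_cells(tree, config.n, int(s_cells))
    B_obs = B_true
    if config.delta > 0:
        B_obs, _ = inject_doublets(B_obs, config.delta, int(s_doub))
    B_obs, _, _ = inject_errors(B_obs, config.beta, config.alpha, int(s_err))
    return tree, B_true, B_obs


@dataclass
class GridSpec:
    """Factor levels of the robustness experiment."""

    n: int = 500
    m_values: Sequence[int] = (10, 25, 50)
    beta_values: Sequence[float] = (0.05, 0.15, 0.25)
    alpha_values: Sequence[float] = (0.001, 0.01)
    delta_values: Sequence[float] = (0.0, 0.2)
    patterns: Sequence[str] = (LINEAR_PATTERN, BRANCHED_PATTERN)
    replicates: int = 5
    time_limit: float = 900.0
    seed: int = 0
    calibration_replicates: int = 1

    def combos(self, patterns: Iterable[str] | None = None):
        for m in self.m_values:
            for beta in self.beta_values:
                for alpha in self.alpha_values:
                    for delta in self.delta_values:
                        for pattern in patterns or self.patterns:
                            yield m, beta, alpha, delta, pattern


def _run_one(
    config: SimulationConfig,
    replicate: int,
    time_limit: float,
    branched_prior: HypothesisParams | None,
) -> dict:
    tree, B_true, B_obs = simulate_instance(config, replicate)
    z = compute_z(B_obs, config.alpha)
    sol = solve_lppf(B_obs, z=z, time_limit=time_limit, seed=config.seed)
    res = classify_solution(
        sol,
        linear=HypothesisParams(*DEFAULT_LINEAR_PRIOR),
        branched=branched_prior,
    )
    return {
        "n": config.n,
        "m": config.m,
        "pattern": config.pattern,
        "beta": config.beta,
        "alpha": config.alpha,
        "delta": config.delta,
        "replicate": replicate,
        "seed": config.seed,
        "z": z,
        "y": res.y,
        "N": res.N,
        "beta_hat": res.beta_hat,
        "K": res.K,
        "label": res.label,
        "truth": config.pattern,
        "status": sol.status,
        "runtime_s": round(sol.runtime_s, 2),
    }


def fit_branched_priors(spec: GridSpec) -> dict[int, HypothesisParams]:
    """Per-m branched priors from an independent branched-only calibration run.

    Runs the branched arm of the grid with a shifted seed (so calibration
    instances are disjoint from evaluation instances), collects β̂, and
    fits a beta distribution by moments separately for each m.
    """
    samples: dict[int, list[float]] = {m: [] for m in spec.m_values}
    for i, (m, beta, alpha, delta, pattern) in enumerate(
        spec.combos([BRANCHED_PATTERN])
    ):
        for rep in range(spec.calibration_replicates):
            cfg = SimulationConfig(
                n=spec.n, m=m, pattern=pattern, beta=beta, alpha=alpha,
                delta=delta, seed=spec.seed + 1_000_003,
            )
            # distinct replicate stream per combo: the fitted prior must see
            # topology-to-topology variation in beta_hat, not just noise
            # variation on one founding tree
            row = _run_one(
                cfg,
                i * spec.calibration_replicates + rep,
                spec.time_limit,
                branched_prior=None,
            )
            bh = row["beta_hat"]
            if 0 < bh < 1:
                samples[m].append(bh)
    priors: dict[int, HypothesisParams] = {}
    for m, vals in samples.items():
        try:
            priors[m] = fit_branched_prior(vals)
        except ValueError:
            # too few / degenerate calibration samples (e.g. a tiny sweep):
            # fall back to the theoretical branched prior
            warnings.warn(
                f"m={m}: calibration produced {len(vals)} usable beta_hat "
                "samples; using the default branched prior instead",
                stacklevel=2,
            )
            priors[m] = HypothesisParams(*DEFAULT_BRANCHED_PRIOR)
    return priors


def run_robustness_grid(
    spec: GridSpec,
    branched_priors: dict[int, HypothesisParams] | None = None,
) -> pd.DataFrame:
    """Full sweep: simulate → budget z → solve → Bayes-factor classify.

    Returns one tidy row per instance.  ``branched_priors`` maps m to the
    fitted branched hypothesis; when omitted it is first estimated via
    :func:`fit_branched_priors`.
    """
    if branched_priors is None:
        branched_priors = fit_branched_priors(spec)
    rows = []
    for m, beta, alpha, delta, pattern in spec.combos():
        for rep in range(spec.replicates):
            cfg = SimulationConfig(
                n=spec.n, m=m, pattern=pattern, beta=beta, alpha=alpha,
                delta=delta, seed=spec.seed,
            )
            rows.append(
                _run_one(cfg, rep, spec.time_limit, branched_priors.get(m))
            )
    return pd.DataFrame(rows)
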