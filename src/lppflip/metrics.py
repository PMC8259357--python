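"""Evaluation statistics: β̂, ancestor–descendant distance, grid summaries.

The ancestor–descendant (AD) distance compares two edge-labeled clonal
trees over the same mutation set: it is the size of the symmetric
difference of their ordered ancestor–descendant mutation-pair sets, where
a pair (x, y) is counted only when x and y sit on *distinct* edges and
x's edge lies on the root path of y's edge.  A linear solution matrix B′
is treated as a path tree whose "edges" are groups of mutations with
identical one-states, ordered by one-state containment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, is_linear


def estimated_beta(y: int, N: int) -> float:
    """Implied false-negative fraction β̂ = y/N (0 when N = 0, with warning)."""
    if y < 0 or N < 0:
        raise ValueError("y and N must be non-negative")
    if y > N:
        raise ValueError(f"y={y} exceeds N={N}")
    if N == 0:
        warnings.warn("N = 0: defining beta_hat as 0", stacklevel=2)
        return 0.0
    return y / N


def ad_pairs(obj) -> set[tuple[str, str]]:
    """Ordered ancestor–descendant mutation pairs of a clone tree or of a
    linear solution matrix.

    Accepts a :class:`~lppflip.simulate.CloneTree` or a complete, linear
    :class:`~lppflip.matrix.GenotypeMatrix`.  Mutations sharing an edge
    (or, for a matrix, an identical one-state) contribute no pair between
    themselves.
    """
    from .simulate import CloneTree  # local import to avoid cycle

    if isinstance(obj, CloneTree):
        return _ad_pairs_tree(obj)
    if isinstance(obj, GenotypeMatrix):
        return _ad_pairs_linear(obj)
    raise TypeError(f"cannot extract AD pairs from {type(obj).__name__}")


def _ad_pairs_tree(tree) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    for clone in range(1, tree.n_clones):
        here = tree.edge_mutations[clone]
        anc = tree.parent[clone]
        ancestors: list[str] = []
        while anc > 0:
            ancestors.extend(tree.edge_mutations[anc])
            anc = tree.parent[anc]
        for y in here:
            for x in ancestors:
                pairs.add((x, y))
    return pairs


def _ad_pairs_linear(B: GenotypeMatrix) -> set[tuple[str, str]]:
    ok, order = is_linear(B)
    if not ok:
        raise ValueError("matrix is not a linear perfect phylogeny")
    # group mutations with identical one-states onto one pseudo-edge
    ones = B.entries == 1
    groups: list[list[int]] = []
    for j in order:  # most-derived first
        if groups and np.array_equal(ones[:, j], ones[:, groups[-1][0]]):
            groups[-1].append(j)
        else:
            groups.append([j])
    groups.reverse()  # root-adjacent first = ancestors first
    pairs: set[tuple[str, str]] = set()
    labels = B.mutation_labels
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            for x in groups[gi]:
                for y in groups[gj]:
                    pairs.add((labels[x], labels[y]))
    return pairs


def _mutation_labels(obj) -> set[str]:
    from .simulate import CloneTree

    if isinstance(obj, CloneTree):
        return {x for muts in obj.edge_mutations for x in muts}
    if isinstance(obj, GenotypeMatrix):
        return set(obj.mutation_labels)
    raise TypeError(f"unsupported operand {type(obj).__name__}")


def ad_distance(t1, t2) -> int:
    """|AD(t1) Δ AD(t2)|: symmetric-difference size of the two pair sets.

    Operands may be clone trees, linear solution matrices, or raw pair
    sets; labeled operands must share one mutation set.
    """
    if isinstance(t1, (set, frozenset)) and isinstance(t2, (set, frozenset)):
        return len(set(t1) ^ set(t2))
    if _mutation_labels(t1) != _mutation_labels(t2):
        raise ValueError("operands have different mutation label sets")
    return len(ad_pairs(t1) ^ ad_pairs(t2))


def confusion_summary(results: pd.DataFrame) -> dict:
    """Overall accuracy, per-class counts, and per-truth medians of β̂ and K.

    Expects the tidy per-instance table produced by the robustness grid
    (columns ``truth``, ``label``, ``beta_hat``, ``K`` at minimum).
    """
    if len(results) == 0:
        raise ValueError("empty results table")
    correct = (results["truth"] == results["label"]).sum()
    counts = (
        results.groupby(["truth", "label"]).size().rename("count").reset_index()
    )
    medians = {}
    for truth, sub in results.groupby("truth"):
        medians[truth] = {
            "median_beta_hat": float(sub["beta_hat"].median()),
            "median_K": float(sub["K"].median()) if "K" in sub else None,
            "n": int(len(sub)),
            "n_correct": int((sub["label"] == truth).sum()),
        }
    return {
        "accuracy": correct / len(results),
        "n": int(len(results)),
        "counts": {
            (r["truth"], r["label"]): int(r["count"]) for _, r in counts.iterrows()
        },
        "by_truth": medians,
    }
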