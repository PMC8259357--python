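"""Genotype-matrix data model and the linear perfect phylogeny check.

A genotype matrix records, for each sequenced single cell (row) and each
somatic single-nucleotide variant (column), whether the variant was observed
in that cell.  Entries are 0 (absent), 1 (present) or MISSING (no usable
reads at that site).  Under the infinite sites assumption the error-free
matrix of a tumor admits a perfect phylogeny; the tumor evolved *linearly*
exactly when the one-states (per-mutation cell sets) can be totally ordered
by set inclusion, i.e. the clonal tree is a path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for an unobserved entry.  File formats use ``3`` or ``?``.
MISSING: int = -1

_ALLOWED = frozenset({0, 1, MISSING})


class MissingEntriesError(ValueError):
    """Raised when an operation that requires a complete matrix sees MISSING."""


@dataclass
class GenotypeMatrix:
    """Observed cells × mutations genotype matrix.

    Parameters
    ----------
    entries
        ``(n, m)`` integer array over ``{0, 1, MISSING}``.
    cell_labels, mutation_labels
        Unique row / column labels; generated (``cell0``..., ``mut0``...)
        when omitted.
    cell_clones
        Optional per-cell true clone assignment (simulation metadata); not
        part of the observed data.
    """

    entries: np.ndarray
    cell_labels: list[str] = field(default=None)  # type: ignore[assignment]
    mutation_labels: list[str] = field(default=None)  # type: ignore[assignment]
    cell_clones: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.ndim != 2:
            raise ValueError("entries must be a 2-D array")
        n, m = self.entries.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one cell and one mutation")
        bad = set(np.unique(self.entries)) - _ALLOWED
        if bad:
            raise ValueError(f"illegal entries {sorted(bad)}; allowed are 0, 1, MISSING")
        if self.cell_labels is None:
            self.cell_labels = [f"cell{i}" for i in range(n)]
        if self.mutation_labels is None:
            self.mutation_labels = [f"mut{j}" for j in range(m)]
        self.cell_labels = [str(x) for x in self.cell_labels]
        self.mutation_labels = [str(x) for x in self.mutation_labels]
        if len(self.cell_labels) != n:
            raise ValueError("cell_labels length does not match row count")
        if len(self.mutation_labels) != m:
            raise ValueError("mutation_labels length does not match column count")
        if len(set(self.cell_labels)) != n:
            raise ValueError("duplicate cell labels")
        if len(set(self.mutation_labels)) != m:
            raise ValueError("duplicate mutation labels")
        if self.cell_clones is not None:
            self.cell_clones = np.asarray(self.cell_clones)
            if self.cell_clones.shape != (n,):
                raise ValueError("cell_clones length does not match row count")

    @property
    def n(self) -> int:
        """Number of cells (rows)."""
        return self.entries.shape[0]

    @property
    def m(self) -> int:
        """Number of mutations (columns)."""
        return self.entries.shape[1]

    @property
    def is_complete(self) -> bool:
        """True when no entry is MISSING."""
        return not bool((self.entries == MISSING).any())

    def ones_count(self) -> int:
        """Number of 1-entries (MISSING excluded)."""
        return int((self.entries == 1).sum())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.entries.copy(),
            list(self.cell_labels),
            list(self.mutation_labels),
            None if self.cell_clones is None else self.cell_clones.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.entries, other.entries)
            and self.cell_labels == other.cell_labels
            and self.mutation_labels == other.mutation_labels
        )


def one_state(B: GenotypeMatrix, j: int) -> set[int]:
    """Cells carrying mutation ``j``: the set ``{i : b_ij = 1}``.

    MISSING entries are not evidence of presence and are excluded.
    """
    if not 0 <= j < B.m:
        raise IndexError(f"mutation index {j} out of range for m={B.m}")
    return set(np.flatnonzero(B.entries[:, j] == 1).tolist())


def is_linear(B: GenotypeMatrix) -> tuple[bool, list[int] | None]:
    """Decide whether ``B`` is a linear perfect phylogeny.

    ``B`` is linear when its one-states admit a total order under set
    inclusion.  Returns ``(True, order)`` with ``order`` listing column
    indices from most-derived (smallest one-state) to root-adjacent
    (largest), or ``(False, None)``.

    Columns are sorted by one-state cardinality (stable on ties, so equal
    one-states keep their column order) and adjacent containment is
    verified; this is sufficient because ``|O_a| <= |O_b|`` and ``O_a ⊆ O_b``
    chain transitively.

    Raises
    ------
    MissingEntriesError
        If any entry is MISSING; linearity of a partial matrix is not
        defined here (imputation is the solver's job).
    """
    if not B.is_complete:
        raise MissingEntriesError("is_linear requires a complete matrix (no MISSING)")
    ones = B.entries == 1
    sizes = ones.sum(axis=0)
    order = np.argsort(sizes, kind="stable")
    for a, b in zip(order[:-1], order[1:]):
        # O_a ⊆ O_b  <=>  no cell with mutation a but not b
        if bool(np.any(ones[:, a] & ~ones[:, b])):
            return False, None
    return True, [int(j) for j in order]
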