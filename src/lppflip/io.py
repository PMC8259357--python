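"""Matrix file formats and read-count discretization.

Matrices are TSV/CSV text with entries 0, 1, and 3 or ``?`` for missing
(the convention of common single-cell SNV callers).  Orientation is rows =
cells, columns = mutations.  An optional header row of mutation labels and
an optional first column of cell labels are auto-detected: any token that
is not a legal entry symbol marks a label.

Read counts are discretized per site with a one-sided binomial exact
test: a site is called mutated when observing at least the seen number of
variant reads is implausible (p < p_cut) under a null sequencing-error
rate; sites with zero total reads are MISSING.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MISSING, GenotypeMatrix

_ENTRY = {"0": 0, "1": 1, "3": MISSING, "?": MISSING}
_OUT = {0: "0", 1: "1", MISSING: "3"}


def _split(line: str, sep: str | None) -> list[str]:
    if sep is None:
        return line.split()
    return [t.strip() for t in line.split(sep)]


def read_matrix(path, sep: str | None = None, transpose: bool = False) -> GenotypeMatrix:
    """Read a genotype matrix, auto-detecting labels and delimiter.

    ``sep=None`` sniffs: tab if present, else comma, else whitespace.
    ``transpose`` flips a mutations × cells file into canonical orientation.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    if sep is None:
        if "\t" in lines[0]:
            sep = "\t"
        elif "," in lines[0]:
            sep = ","
    rows = [_split(ln, sep) for ln in lines]

    def is_entry(tok: str) -> bool:
        return tok in _ENTRY

    # header iff the first row holds no legal entry symbols at all — a mixed
    # row is treated as (possibly malformed) data
    header = not any(is_entry(t) for t in rows[0])
    body = rows[1:] if header else rows
    if not body:
        raise ValueError(f"{path}: no data rows")
    labeled_rows = not all(is_entry(r[0]) for r in body)
    cell_labels = [r[0] for r in body] if labeled_rows else None
    data_rows = [r[1:] if labeled_rows else r for r in body]
    if len({len(r) for r in data_rows}) != 1:
        raise ValueError(f"{path}: ragged rows")
    if header:
        hdr = rows[0]
        mutation_labels = hdr[1:] if len(hdr) == len(data_rows[0]) + 1 else hdr
        if len(mutation_labels) != len(data_rows[0]):
            raise ValueError(f"{path}: header width does not match data width")
    else:
        mutation_labels = None
    entries = np.empty((len(data_rows), len(data_rows[0])), dtype=np.int8)
    for i, r in enumerate(data_rows):
        for j, tok in enumerate(r):
            if tok not in _ENTRY:
                raise ValueError(f"{path}: illegal symbol {tok!r} at row {i}, col {j}")
            entries[i, j] = _ENTRY[tok]
    B = GenotypeMatrix(entries, cell_labels, mutation_labels)
    if transpose:
        B = GenotypeMatrix(B.entries.T, B.mutation_labels, B.cell_labels)
    return B


def write_matrix(B: GenotypeMatrix, path, sep: str = "\t", labels: bool = True) -> None:
    """Write ``B`` losslessly (MISSING as 3); inverse of :func:`read_matrix`."""
    with open(path, "w") as fh:
        if labels:
            fh.write(sep.join(["cell"] + B.mutation_labels) + "\n")
        for i in range(B.n):
            row = [_OUT[int(v)] for v in B.entries[i]]
            if labels:
                row = [B.cell_labels[i]] + row
            fh.write(sep.join(row) + "\n")


def read_ms_output(path) -> list[GenotypeMatrix]:
    """Read coalescent-simulator (``ms``-style) output into genotype matrices.

    Each replicate block after a ``//`` line contributes one matrix: the
    ``segsites:`` count, an optional ``positions:`` line, then one 0/1
    haplotype string per sampled chromosome (rows = cells, columns =
    segregating sites).
    """
    matrices: list[GenotypeMatrix] = []
    block: list[str] = []
    in_block = False
    for raw in Path(path).read_text().splitlines() + ["//"]:
        line = raw.strip()
        if line == "//":
            if block:
                entries = np.array(
                    [[int(ch) for ch in row] for row in block], dtype=np.int8
                )
                matrices.append(GenotypeMatrix(entries))
                block = []
            in_block = True
            continue
        if not in_block or not line or line.startswith(("segsites", "positions")):
            continue
        if set(line) <= {"0", "1"}:
            block.append(line)
    if not matrices:
        raise ValueError(f"{path}: no replicate blocks found")
    return matrices


@dataclass
class ReadCountTable:
    """Per-(cell, site) variant and total read counts."""

    variant: np.ndarray
    total: np.ndarray
    cell_labels: list[str] | None = None
    mutation_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.variant = np.asarray(self.variant, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.variant.shape != self.total.shape or self.variant.ndim != 2:
            raise ValueError("variant and total must be 2-D arrays of equal shape")
        if (self.variant < 0).any() or (self.total < 0).any():
            raise ValueError("read counts must be non-negative")
        if (self.variant > self.total).any():
            raise ValueError("variant reads exceed total reads somewhere")

    @classmethod
    def from_files(cls, variant_path, total_path, sep: str = "\t") -> "ReadCountTable":
        v = pd.read_csv(variant_path, sep=sep, index_col=0)
        t = pd.read_csv(total_path, sep=sep, index_col=0)
        if list(v.index) != list(t.index) or list(v.columns) != list(t.columns):
            raise ValueError("variant and total tables have mismatched labels")
        return cls(
            v.to_numpy(), t.to_numpy(), [str(x) for x in v.index], [str(x) for x in v.columns]
        )


def discretize_counts(
    table: ReadCountTable, null_rate: float = 0.001, p_cut: float = 1e-6
) -> GenotypeMatrix:
    """Call genotypes from read counts with a one-sided binomial exact test.

    Entry is MISSING when total = 0; otherwise 1 iff
    ``P(X >= variant | X ~ Binomial(total, null_rate)) < p_cut`` — the
    "greater" alternative, since false-positive sequencing error inflates
    variant reads — and 0 otherwise.
    """
    if not 0 < null_rate < 1:
        raise ValueError("null_rate must be in (0, 1)")
    v, t = table.variant, table.total
    pvals = stats.binom.sf(v - 1, np.maximum(t, 1), null_rate)
    entries = np.where(pvals < p_cut, 1, 0).astype(np.int8)
    entries[t == 0] = MISSING
    return GenotypeMatrix(entries, table.cell_labels, table.mutation_labels)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")
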