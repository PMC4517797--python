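"""Binary entity-pair × dependency-path co-occurrence matrices.

The central data structure of the pipeline: a binary matrix ``M`` whose rows
are drug-gene pairs and whose columns are canonical dependency-path strings.
``M[i, j] = 1`` iff pair *i* was connected by path *j* at least once in the
corpus. Rows and columns carry their total corpus occurrence counts as
metadata, because the dense/sparse dataset presets filter on those corpus
counts, not on matrix row sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import scipy.sparse as sp

__all__ = [
    "TripletRecord",
    "CooccurrenceMatrix",
    "EmptyMatrixError",
    "MatrixParseError",
    "build_matrix",
    "matrix_stats",
    "read_triplets",
    "write_triplets",
    "PRESETS",
]

#: Filtering presets: (min_pair_occurrences, min_path_occurrences).
#: "dense" keeps pairs and paths seen at least five times in the corpus;
#: "sparse" keeps paths seen at least twice and every pair they connect.
PRESETS = {"dense": (5, 5), "sparse": (1, 2)}


class EmptyMatrixError(ValueError):
    """Raised when filtering leaves no surviving rows or columns."""


class MatrixParseError(ValueError):
    """Raised on a malformed sparse-matrix file; carries the line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class TripletRecord:
    """One aggregated (drug, gene, path) key with its corpus occurrence count."""

    drug: str
    gene: str
    path: str
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug, self.gene)


class CooccurrenceMatrix:
    """Binary co-occurrence matrix with label registries.

    Parameters
    ----------
    data : scipy.sparse matrix
        Binary n×m matrix (any sparse format; stored as CSR of int8).
    row_labels : sequence of (drug, gene) tuples
    col_labels : sequence of canonical path strings
    row_counts, col_counts : array-like of int, optional
        Corpus occurrence totals for each row / column. Defaults to the
        matrix margins when not supplied.
    """

    def __init__(self, data, row_labels, col_labels, row_counts=None, col_counts=None):
        data = sp.csr_matrix(data, dtype=np.int8)
        data.eliminate_zeros()
        if data.nnz and data.data.max() > 1:
            raise ValueError("entries must be binary")
        n, m = data.shape
        if n < 1 or m < 1:
            raise EmptyMatrixError("matrix must have at least one row and column")
        row_labels = [tuple(r) for r in row_labels]
        col_labels = list(col_labels)
        if len(row_labels) != n or len(col_labels) != m:
            raise ValueError("label count does not match matrix shape")
        if len(set(row_labels)) != n:
            raise ValueError("duplicate row labels")
        if len(set(col_labels)) != m:
            raise ValueError("duplicate column labels")
        margins = np.asarray(data.sum(axis=1)).ravel()
        if (margins == 0).any():
            raise ValueError("all-zero row present; drop before construction")
        if (np.asarray(data.sum(axis=0)).ravel() == 0).any():
            raise ValueError("all-zero column present; drop before construction")
        self.data = data
        self.row_labels = row_labels
        self.col_labels = col_labels
        self.row_counts = (
            np.asarray(row_counts, dtype=np.int64)
            if row_counts is not None
            else np.asarray(data.sum(axis=1), dtype=np.int64).ravel()
        )
        self.col_counts = (
            np.asarray(col_counts, dtype=np.int64)
            if col_counts is not None
            else np.asarray(data.sum(axis=0), dtype=np.int64).ravel()
        )
        self._row_index = {lab: i for i, lab in enumerate(row_labels)}
        self._col_index = {lab: j for j, lab in enumerate(col_labels)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.data.shape[1]

    @property
    def nnz(self) -> int:
        return int(self.data.nnz)

    def row_index(self, label) -> int:
        return self._row_index[tuple(label)]

    def row_indices(self, labels) -> np.ndarray:
        return np.array([self.row_index(l) for l in labels], dtype=np.intp)

    def toarray(self) -> np.ndarray:
        return self.data.toarray().astype(float)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CooccurrenceMatrix):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and (self.data != other.data).nnz == 0
            and np.array_equal(self.row_counts, other.row_counts)
            and np.array_equal(self.col_counts, other.col_counts)
        )

    def __repr__(self) -> str:
        return f"<CooccurrenceMatrix {self.n}x{self.m}, nnz={self.nnz}>"

    # -- serialization -----------------------------------------------------
    def save(self, destination) -> None:
        """Write in the sparse text format (see module docs).

        Layout: ``#rows N`` / ``#cols M`` headers, N row-label lines
        (``drug<TAB>gene<TAB>count``), M column-label lines
        (``path<TAB>count``), then one 0-based ``i<TAB>j`` line per nonzero.
        """
        close = False
        if not hasattr(destination, "write"):
            destination = open(destination, "w", encoding="utf-8")
            close = True
        try:
            w = destination.write
            w(f"#rows {self.n}\n")
            w(f"#cols {self.m}\n")
            for (d, g), c in zip(self.row_labels, self.row_counts):
                w(f"{d}\t{g}\t{int(c)}\n")
            for p, c in zip(self.col_labels, self.col_counts):
                w(f"{p}\t{int(c)}\n")
            coo = self.data.tocoo()
            order = np.lexsort((coo.col, coo.row))
            for i, j in zip(coo.row[order], coo.col[order]):
                w(f"{i}\t{j}\n")
        finally:
            if close:
                destination.close()

    @classmethod
    def load(cls, source) -> "CooccurrenceMatrix":
        """Read a matrix written by :meth:`save`; raises MatrixParseError."""
        close = False
        if not hasattr(source, "read"):
            source = open(source, "r", encoding="utf-8")
            close = True
        try:
            lines = source.read().splitlines()
        finally:
            if close:
                source.close()
        pos = 0

        def expect_header(name: str) -> int:
            nonlocal pos
            if pos >= len(lines) or not lines[pos].startswith(f"#{name} "):
                raise MatrixParseError(f"expected '#{name} N' header", pos + 1)
            try:
                value = int(lines[pos].split(" ", 1)[1])
            except ValueError:
                raise MatrixParseError(f"non-integer {name} count", pos + 1) from None
            pos += 1
            return value

        n = expect_header("rows")
        m = expect_header("cols")
        row_labels, row_counts = [], []
        for _ in range(n):
            if pos >= len(lines):
                raise MatrixParseError("unexpected end of file in row labels", pos + 1)
            parts = lines[pos].split("\t")
            if len(parts) != 3:
                raise MatrixParseError("row label needs drug<TAB>gene<TAB>count", pos + 1)
            row_labels.append((parts[0], parts[1]))
            try:
                row_counts.append(int(parts[2]))
            except ValueError:
                raise MatrixParseError("non-integer row count", pos + 1) from None
            pos += 1
        col_labels, col_counts = [], []
        for _ in range(m):
            if pos >= len(lines):
                raise MatrixParseError("unexpected end of file in column labels", pos + 1)
            parts = lines[pos].split("\t")
            if len(parts) != 2:
                raise MatrixParseError("column label needs path<TAB>count", pos + 1)
            col_labels.append(parts[0])
            try:
                col_counts.append(int(parts[1]))
            except ValueError:
                raise MatrixParseError("non-integer column count", pos + 1) from None
            pos += 1
        rows, cols, seen = [], [], set()
        for line in lines[pos:]:
            pos += 1
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MatrixParseError("coordinate needs i<TAB>j", pos)
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                raise MatrixParseError("non-integer coordinate", pos) from None
            if not (0 <= i < n and 0 <= j < m):
                raise MatrixParseError(f"coordinate ({i},{j}) out of bounds {n}x{m}", pos)
            if (i, j) in seen:
                raise MatrixParseError(f"duplicate entry ({i},{j})", pos)
            seen.add((i, j))
            rows.append(i)
            cols.append(j)
        data = sp.coo_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, m)
        )
        return cls(data, row_labels, col_labels, row_counts, col_counts)


def build_matrix(
    records: Iterable[TripletRecord],
    min_pair_occurrences: int = 1,
    min_path_occurrences: int = 1,
) -> CooccurrenceMatrix:
    """Build a binary matrix from aggregated triplets, applying corpus-count filters.

    A path's occurrence count is the sum of record counts over all pairs it
    connects; a pair's occurrence count is the sum over all its paths. Paths
    are filtered first, then pairs, and rows/columns emptied by the combined
    filter are dropped once (no fixpoint iteration). Both filters read the
    *corpus* occurrence totals, which are retained as metadata.
    """
    records = list(records)
    seen_keys: set[tuple[str, str, str]] = set()
    pair_totals: dict[tuple[str, str], int] = {}
    path_totals: dict[str, int] = {}
    for r in records:
        key = (r.drug, r.gene, r.path)
        if key in seen_keys:
            raise ValueError(f"duplicate (drug, gene, path) key: {key}; aggregate first")
        seen_keys.add(key)
        pair_totals[r.pair] = pair_totals.get(r.pair, 0) + r.count
        path_totals[r.path] = path_totals.get(r.path, 0) + r.count

    keep_paths = {p for p, c in path_totals.items() if c >= min_path_occurrences}
    if not keep_paths:
        raise EmptyMatrixError(
            f"no dependency path occurred >= {min_path_occurrences} times"
        )
    keep_pairs = {p for p, c in pair_totals.items() if c >= min_pair_occurrences}
    if not keep_pairs:
        raise EmptyMatrixError(f"no pair occurred >= {min_pair_occurrences} times")

    surviving = [r for r in records if r.pair in keep_pairs and r.path in keep_paths]
    if not surviving:
        raise EmptyMatrixError(
            "thresholds "
            f"(pair>={min_pair_occurrences}, path>={min_path_occurrences}) "
            "left no surviving entries"
        )
    # Drop rows/columns emptied by the joint filter (single pass).
    live_pairs = sorted({r.pair for r in surviving})
    live_paths = sorted({r.path for r in surviving})
    ri = {p: i for i, p in enumerate(live_pairs)}
    ci = {p: j for j, p in enumerate(live_paths)}
    rows = [ri[r.pair] for r in surviving]
    cols = [ci[r.path] for r in surviving]
    data = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(live_pairs), len(live_paths)),
    )
    return CooccurrenceMatrix(
        data,
        live_pairs,
        live_paths,
        row_counts=[pair_totals[p] for p in live_pairs],
        col_counts=[path_totals[p] for p in live_paths],
    )


def matrix_stats(matrix: CooccurrenceMatrix) -> tuple[int, int, int, float]:
    """Return (n, m, nonzero count, sparsity %), sparsity to one decimal."""
    n, m, nnz = matrix.n, matrix.m, matrix.nnz
    sparsity = round(100.0 * (1.0 - nnz / (n * m)), 1)
    return n, m, nnz, sparsity


def read_triplets(source) -> list[TripletRecord]:
    """Read ``drug<TAB>gene<TAB>path<TAB>count`` lines."""
    close = False
    if not hasattr(source, "read"):
        source = open(source, "r", encoding="utf-8")
        close = True
    try:
        out = []
        for ln, line in enumerate(source, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise MatrixParseError("expected drug<TAB>gene<TAB>path<TAB>count", ln)
            out.append(TripletRecord(parts[0], parts[1], parts[2], int(parts[3])))
        return out
    finally:
        if close:
            source.close()


def write_triplets(records: Sequence[TripletRecord], destination) -> None:
    close = False
    if not hasattr(destination, "write"):
        destination = open(destination, "w", encoding="utf-8")
        close = True
    try:
        for r in records:
            destination.write(f"{r.drug}\t{r.gene}\t{r.path}\t{r.count}\n")
    finally:
        if close:
            destination.close()
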