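"""Ensemble of ITCC runs and co-clustering counts.

A single ITCC run is a noisy, locally-optimal guess at which rows (and
columns) belong together. Running the algorithm N times from different
random initializations and counting, for every pair of rows, the number of
runs in which they shared a row cluster yields the n×n consensus matrix C.
C/N is the co-clustering frequency — the similarity measure everything
downstream (seeded scoring, the relationship landscape) is built on.

The run schedule is ``base_seed + i`` for run i, so the resulting C is
independent of execution order and reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .itcc import ITCC, ITCCResults
from .matrix import CooccurrenceMatrix

__all__ = ["CoclusterCounts", "run_ensemble", "EBC", "EBCResults"]


@dataclass
class CoclusterCounts:
    """Symmetric integer count matrix over one axis of the data matrix.

    Invariants: C = Cᵀ, 0 ≤ C_ij ≤ N, C_ii = N.
    """

    counts: np.ndarray
    n_runs: int
    axis: str  # "rows" | "columns"
    labels: list

    def __post_init__(self):
        C = np.asarray(self.counts)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("counts must be square")
        if not np.array_equal(C, C.T):
            raise ValueError("counts must be symmetric")
        if C.min() < 0 or C.max() > self.n_runs:
            raise ValueError("counts out of [0, N]")
        if not np.all(np.diag(C) == self.n_runs):
            raise ValueError("diagonal must equal N")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_runs

    def index(self, label) -> int:
        try:
            return self.labels.index(tuple(label) if isinstance(label, (list, tuple)) else label)
        except ValueError:
            raise KeyError(f"label {label!r} not in counts") from None

    # -- serialization (sparse coordinate dialect with an N header) --------
    def save(self, destination) -> None:
        close = False
        if not hasattr(destination, "write"):
            destination = open(destination, "w", encoding="utf-8")
            close = True
        try:
            w = destination.write
            w(f"#runs {self.n_runs}\n")
            w(f"#axis {self.axis}\n")
            w(f"#size {self.n}\n")
            for lab in self.labels:
                if isinstance(lab, tuple):
                    w("\t".join(lab) + "\n")
                else:
                    w(f"{lab}\n")
            C = self.counts
            for i in range(self.n):
                for j in range(i, self.n):
                    if C[i, j]:
                        w(f"{i}\t{j}\t{int(C[i, j])}\n")
        finally:
            if close:
                destination.close()

    @classmethod
    def load(cls, source) -> "CoclusterCounts":
        close = False
        if not hasattr(source, "read"):
            source = open(source, "r", encoding="utf-8")
            close = True
        try:
            lines = source.read().splitlines()
        finally:
            if close:
                source.close()
        if len(lines) < 3 or not lines[0].startswith("#runs "):
            raise ValueError("missing #runs header")
        n_runs = int(lines[0].split(" ", 1)[1])
        axis = lines[1].split(" ", 1)[1]
        size = int(lines[2].split(" ", 1)[1])
        labels = []
        for line in lines[3 : 3 + size]:
            parts = line.split("\t")
            labels.append(tuple(parts) if len(parts) > 1 else parts[0])
        C = np.zeros((size, size), dtype=np.int64)
        for line in lines[3 + size :]:
            if not line:
                continue
            i, j, v = line.split("\t")
            i, j, v = int(i), int(j), int(v)
            C[i, j] = v
            C[j, i] = v
        return cls(C, n_runs, axis, labels)


def _accumulate(C: np.ndarray, assign: np.ndarray) -> None:
    for c in np.unique(assign):
        members = np.flatnonzero(assign == c)
        C[np.ix_(members, members)] += 1


def run_ensemble(
    matrix: CooccurrenceMatrix,
    k: int,
    l: int,
    n_runs: int,
    base_seed: int = 0,
    axis: str = "rows",
    max_iter: int = 50,
    tol: float = 1e-6,
):
    """Run ITCC ``n_runs`` times (seeds base_seed + i) and count co-clusterings.

    Returns a :class:`CoclusterCounts` for axis "rows" or "columns", or a
    tuple (rows_counts, columns_counts) for axis "both" computed from the
    same set of runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if axis not in ("rows", "columns", "both"):
        raise ValueError("axis must be 'rows', 'columns' or 'both'")
    model = ITCC(matrix, k, l, max_iter=max_iter, tol=tol)
    want_rows = axis in ("rows", "both")
    want_cols = axis in ("columns", "both")
    Cr = np.zeros((matrix.n, matrix.n), dtype=np.int64) if want_rows else None
    Cc = np.zeros((matrix.m, matrix.m), dtype=np.int64) if want_cols else None
    for i in range(n_runs):
        res = model.fit(base_seed + i)
        if want_rows:
            _accumulate(Cr, res.row_assign)
        if want_cols:
            _accumulate(Cc, res.col_assign)
    rows = CoclusterCounts(Cr, n_runs, "rows", list(matrix.row_labels)) if want_rows else None
    cols = CoclusterCounts(Cc, n_runs, "columns", list(matrix.col_labels)) if want_cols else None
    if axis == "rows":
        return rows
    if axis == "columns":
        return cols
    return rows, cols


class EBC:
    """Ensemble biclustering model: N seeded ITCC runs on one matrix.

    The fitted results expose the co-clustering count matrix together with
    seeded rank-sum scoring and the correlation-distance landscape.

    Parameters
    ----------
    matrix : CooccurrenceMatrix
    k, l : int
        Cluster numbers for every ITCC run.
    n_runs : int
        Ensemble size N (the reference analyses used N = 2000; performance
        stabilizes around N ≈ 1000 on literature-scale matrices).
    """

    def __init__(self, matrix: CooccurrenceMatrix, k: int, l: int,
                 n_runs: int = 2000, max_iter: int = 50, tol: float = 1e-6):
        self.matrix = matrix
        self.k = int(k)
        self.l = int(l)
        self.n_runs = int(n_runs)
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, seed: int = 0, axis: str = "rows") -> "EBCResults":
        counts = run_ensemble(
            self.matrix, self.k, self.l, self.n_runs, base_seed=seed,
            axis=axis, max_iter=self.max_iter, tol=self.tol,
        )
        row_counts, col_counts = (counts if axis == "both"
                                  else (counts, None) if axis == "rows"
                                  else (None, counts))
        return EBCResults(model=self, seed=seed, counts=row_counts,
                          column_counts=col_counts)


@dataclass
class EBCResults:
    """Fitted ensemble: consensus counts plus scoring and landscape views."""

    model: EBC
    seed: int
    counts: CoclusterCounts | None
    column_counts: CoclusterCounts | None = None

    def score(self, seed_set, method: str = "ebc", tie_seed: int = 0,
              lsa_rank: int | None = None):
        """Score all non-seed rows against ``seed_set``; returns a DataFrame."""
        from .scoring import score_candidates

        return score_candidates(
            self.model.matrix, seed_set, method=method, counts=self.counts,
            tie_seed=tie_seed, lsa_rank=lsa_rank,
        )

    def distance_matrix(self) -> np.ndarray:
        from .landscape import cocluster_distance

        return cocluster_distance(self.counts)

    def linkage(self):
        from .landscape import minimax_linkage

        return minimax_linkage(self.distance_matrix(),
                               labels=self.counts.labels)

    def summary(self) -> str:
        freq = self.counts.frequencies() if self.counts is not None else None
        lines = [
            "Ensemble biclustering results",
            "=" * 34,
            f"matrix           {self.model.matrix.n} x {self.model.matrix.m}",
            f"k, l             {self.model.k}, {self.model.l}",
            f"runs (N)         {self.model.n_runs}",
            f"base seed        {self.seed}",
        ]
        if freq is not None:
            off = freq[~np.eye(freq.shape[0], dtype=bool)]
            lines.append(f"mean off-diagonal co-clustering frequency  {off.mean():.3f}")
        return "\n".join(lines)
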