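"""Synthetic binary matrices with planted bicluster structure.

Two generators:

* :func:`planted_matrix` — rows and columns are partitioned into blocks; a
  cell is Bernoulli(p_in) when its row block is associated with its column
  block and Bernoulli(p_out) otherwise. Ground-truth block memberships are
  returned for recovery checks.

* :func:`synonymy_scenario` — the situation that motivates ensemble
  co-clustering: one positive relationship class whose surface forms fall
  into two *disjoint* column blocks ("synonymous" path families). The
  positive rows split in half: split A rows only ever use column block A,
  split B rows only block B, so their row vectors share no nonzero columns
  and any cosine between splits is exactly zero. Negative rows live in two
  separate sub-groups, each with its own wider column block, so that at
  k = l = 3 the cheapest mutual-information merge is the two positive
  column blocks — the structural cue that lets an ITCC ensemble co-cluster
  the two splits while cosine methods see nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .matrix import CooccurrenceMatrix

__all__ = ["PlantedSpec", "planted_matrix", "SynonymyData", "synonymy_scenario"]


@dataclass(frozen=True)
class PlantedSpec:
    """Planted row-block × column-block Bernoulli structure.

    ``association`` maps a row-block index to the column blocks it is
    expressed through; cells inside an association are 1 with probability
    ``p_in``, all other cells with ``p_out``.
    """

    row_block_sizes: tuple[int, ...]
    col_block_sizes: tuple[int, ...]
    association: Mapping[int, Sequence[int]]
    p_in: float
    p_out: float
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if any(s <= 0 for s in self.row_block_sizes + self.col_block_sizes):
            raise ValueError("block sizes must be positive")
        n_rb, n_cb = len(self.row_block_sizes), len(self.col_block_sizes)
        for rb, cbs in self.association.items():
            if not (0 <= rb < n_rb):
                raise ValueError(f"row block {rb} out of range")
            for cb in cbs:
                if not (0 <= cb < n_cb):
                    raise ValueError(f"column block {cb} out of range")


def _block_labels(sizes: Sequence[int]) -> np.ndarray:
    return np.repeat(np.arange(len(sizes)), sizes)


def planted_matrix(spec: PlantedSpec):
    """Sample a planted matrix; returns (matrix, row truth, column truth).

    Empty rows/columns are resampled once and then dropped (with their
    truth entries) so downstream code never sees an all-zero margin.
    """
    rng = np.random.default_rng(spec.seed)
    row_truth = _block_labels(spec.row_block_sizes)
    col_truth = _block_labels(spec.col_block_sizes)
    n, m = row_truth.size, col_truth.size
    prob = np.full((n, m), spec.p_out)
    for rb, cbs in spec.association.items():
        rows = row_truth == rb
        for cb in cbs:
            prob[np.ix_(rows, col_truth == cb)] = spec.p_in

    M = (rng.random((n, m)) < prob).astype(np.int8)
    for _ in range(1):  # resample empty margins once
        empty_rows = np.flatnonzero(M.sum(axis=1) == 0)
        for r in empty_rows:
            M[r] = rng.random(m) < prob[r]
        empty_cols = np.flatnonzero(M.sum(axis=0) == 0)
        for c in empty_cols:
            M[:, c] = rng.random(n) < prob[:, c]
    keep_rows = M.sum(axis=1) > 0
    keep_cols = M.sum(axis=0) > 0
    M = M[np.ix_(keep_rows, keep_cols)]
    row_truth = row_truth[keep_rows]
    col_truth = col_truth[keep_cols]
    row_ids = np.flatnonzero(keep_rows)
    col_ids = np.flatnonzero(keep_cols)
    matrix = CooccurrenceMatrix(
        sp.csr_matrix(M),
        [(f"drug{r:04d}", f"gene{r:04d}") for r in row_ids],
        [f"path{c:04d}" for c in col_ids],
    )
    return matrix, row_truth, col_truth


@dataclass
class SynonymyData:
    """Synonymy-scenario sample with its ground-truth row groups."""

    matrix: CooccurrenceMatrix
    split_a: list  # positive rows supported on column block A only
    split_b: list  # positive rows supported on column block B only
    negatives: list  # labeled negative rows
    bridges: list  # unlabeled rows whose support spans both A and B
    background: list  # unlabeled filler community rows

    @property
    def positives(self) -> list:
        return self.split_a + self.split_b


def synonymy_scenario(
    rows_per_split: int = 40,
    cols_per_surface_form: int = 6,
    p_in: float = 0.9,
    p_out: float = 0.0,
    seed: int = 0,
    n_bridge_rows: int = 12,
    n_communities: int = 4,
    community_rows: int = 20,
    community_width: int = 18,
) -> SynonymyData:
    """One relationship class expressed through two disjoint column families.

    Layout (defaults): ``rows_per_split`` positive rows per split; split A
    is Bernoulli(p_in) on the first ``cols_per_surface_form`` columns only,
    split B on the next block only, so the two splits share no nonzero
    column and every cross-split cosine is exactly 0. A small set of
    *bridge* rows — unlabeled pairs whose sentences happen to use both
    surface forms — is Bernoulli(p_in) across both positive blocks; these
    are what make the two path families distributionally similar, the cue
    co-clustering exploits. The rest of the corpus is ``n_communities``
    unrelated relationship communities (``community_rows`` rows ×
    ``community_width`` columns each, Bernoulli(p_in) on their own block);
    the first two communities are the labeled negatives, the rest unlabeled
    background. ``p_out`` adds Bernoulli background noise for bridge and
    community rows inside the community column pool; positive rows carry
    no noise, keeping the cross-split disjointness structural (it is
    re-verified before returning).
    """
    if rows_per_split < 1:
        raise ValueError("rows_per_split must be >= 1")
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if n_communities < 2:
        raise ValueError("need at least two communities for labeled negatives")
    rng = np.random.default_rng(seed)
    c = cols_per_surface_form
    n = 2 * rows_per_split + n_bridge_rows + n_communities * community_rows
    m = 2 * c + n_communities * community_width

    M = np.zeros((n, m), dtype=np.int8)
    a_rows = slice(0, rows_per_split)
    b_rows = slice(rows_per_split, 2 * rows_per_split)
    br_rows = slice(2 * rows_per_split, 2 * rows_per_split + n_bridge_rows)
    comm_start = br_rows.stop

    M[a_rows, 0:c] = rng.random((rows_per_split, c)) < p_in
    M[b_rows, c:2 * c] = rng.random((rows_per_split, c)) < p_in
    M[br_rows, 0:2 * c] = rng.random((n_bridge_rows, 2 * c)) < p_in
    if p_out > 0:
        shape = (n - comm_start + n_bridge_rows, m - 2 * c)
        M[br_rows.start:, 2 * c:] = rng.random(shape) < p_out
    for g in range(n_communities):
        r0 = comm_start + g * community_rows
        c0 = 2 * c + g * community_width
        block = rng.random((community_rows, community_width)) < p_in
        M[r0:r0 + community_rows, c0:c0 + community_width] |= block

    # Resample empty rows once within their own block, then require success.
    own_block = {}
    for r in range(n):
        if r < b_rows.start:
            own_block[r] = (0, c)
        elif r < br_rows.start:
            own_block[r] = (c, 2 * c)
        elif r < comm_start:
            own_block[r] = (0, 2 * c)
        else:
            g = (r - comm_start) // community_rows
            own_block[r] = (2 * c + g * community_width,
                            2 * c + (g + 1) * community_width)
    for r in range(n):
        if M[r].sum() == 0:
            lo, hi = own_block[r]
            M[r, lo:hi] = rng.random(hi - lo) < p_in
    if (M.sum(axis=1) == 0).any() or (M.sum(axis=0) == 0).any():
        raise ValueError(
            "parameters produced empty rows/columns even after resampling; "
            "increase p_in or block widths"
        )

    # Structural guarantee: no split-A row shares a nonzero column with split B.
    shared = (M[a_rows].sum(axis=0) > 0) & (M[b_rows].sum(axis=0) > 0)
    if shared.any():
        raise ValueError("cross-split column support is not disjoint")

    matrix = CooccurrenceMatrix(
        sp.csr_matrix(M),
        [(f"drug{r:04d}", f"gene{r:04d}") for r in range(n)],
        [f"path{j:04d}" for j in range(m)],
    )
    labels = matrix.row_labels
    neg_stop = comm_start + 2 * community_rows
    return SynonymyData(
        matrix=matrix,
        split_a=labels[a_rows],
        split_b=labels[b_rows],
        negatives=labels[comm_start:neg_stop],
        bridges=labels[br_rows],
        background=labels[neg_stop:],
    )
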