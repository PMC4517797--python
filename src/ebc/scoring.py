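"""Seeded scoring of candidate rows.

Given a seed set S of rows exemplifying a relationship of interest, each
candidate row T_i is scored by how strongly it resembles the seeds:

* ``ebc``      — rank all n rows by their co-clustering count with T_i
  (most frequent co-clusterer gets rank n, ties broken by a seeded random
  permutation) and sum the ranks of the seed members. Ranks, rather than
  raw counts, remove each row's baseline "promiscuity".
* ``avgcos``   — mean cosine similarity between T_i's binary row vector
  and the seed row vectors.
* ``ranksum``  — the same rank-sum formula with the ranking produced by
  cosine similarity instead of co-clustering counts.
* ``lsa_*``    — the two cosine methods applied to rank-r SVD row
  embeddings (latent semantic analysis) instead of raw rows.

Raw scores are normalized to a [0, 1] "relative certainty" by min-max
scaling, so the strongest candidate always reads 1.000.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ensemble import CoclusterCounts
from .matrix import CooccurrenceMatrix

__all__ = [
    "ebc_score",
    "avg_cosine_score",
    "ranksum_cosine_score",
    "lsa_embed",
    "relative_certainty",
    "score_candidates",
]


def _ranks_with_random_ties(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ascending ranks 1..n; equal values are ordered by a random permutation."""
    values = np.asarray(values, dtype=float)
    n = values.size
    tiebreak = rng.permutation(n)
    order = np.lexsort((tiebreak, values))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def _check_seed_set(S_idx: np.ndarray, t_idx: int) -> None:
    if S_idx.size == 0:
        raise ValueError("seed set must be non-empty")
    if t_idx in set(S_idx.tolist()):
        raise ValueError("candidate row is a member of the seed set")


def ebc_score(counts: CoclusterCounts, seed_indices, t_index: int,
              tie_seed: int = 0) -> int:
    """Rank-sum of the seed set within the co-clustering ranking of T_i.

    All n rows (including T_i itself, which takes the top rank through its
    diagonal count N but contributes nothing because T_i ∉ S) are ranked by
    C(·, T_i); score = Σ_j j · 1{rank j is a seed member}.
    """
    S_idx = np.asarray(seed_indices, dtype=np.intp)
    _check_seed_set(S_idx, t_index)
    rng = np.random.default_rng([tie_seed, t_index])
    ranks = _ranks_with_random_ties(counts.counts[:, t_index], rng)
    return int(ranks[S_idx].sum())


def _row_vectors(matrix_or_array) -> np.ndarray:
    if isinstance(matrix_or_array, CooccurrenceMatrix):
        return matrix_or_array.toarray()
    if sp.issparse(matrix_or_array):
        return matrix_or_array.toarray().astype(float)
    return np.asarray(matrix_or_array, dtype=float)


def _cosine_to_all(V: np.ndarray, t_index: int) -> np.ndarray:
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"row {bad} has zero norm; cosine undefined")
    return (V @ V[t_index]) / (norms * norms[t_index])


def avg_cosine_score(matrix, seed_indices, t_index: int) -> float:
    """Mean cosine similarity of T_i's row vector with the seed row vectors."""
    S_idx = np.asarray(seed_indices, dtype=np.intp)
    _check_seed_set(S_idx, t_index)
    V = _row_vectors(matrix)
    cos = _cosine_to_all(V, t_index)
    return float(cos[S_idx].mean())


def ranksum_cosine_score(matrix, seed_indices, t_index: int,
                         tie_seed: int = 0) -> int:
    """Rank-sum of the seed set within the cosine-similarity ranking of T_i."""
    S_idx = np.asarray(seed_indices, dtype=np.intp)
    _check_seed_set(S_idx, t_index)
    V = _row_vectors(matrix)
    cos = _cosine_to_all(V, t_index)
    rng = np.random.default_rng([tie_seed, t_index])
    ranks = _ranks_with_random_ties(cos, rng)
    return int(ranks[S_idx].sum())


def lsa_embed(matrix, r: int) -> np.ndarray:
    """Rank-r SVD row embeddings U_r · diag(s_r) of the binary matrix.

    At r = min(n, m) the embeddings reproduce every pairwise row cosine of
    the original matrix exactly.
    """
    V = _row_vectors(matrix)
    n, m = V.shape
    if not (1 <= r <= min(n, m)):
        raise ValueError(f"embedding rank r={r} out of range [1, {min(n, m)}]")
    U, s, _ = np.linalg.svd(V, full_matrices=False)
    return U[:, :r] * s[:r]


def relative_certainty(scores) -> np.ndarray:
    """Min-max normalization to [0, 1]; a constant vector maps to all ones."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one score")
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.ones_like(scores)
    return (scores - lo) / (hi - lo)


def score_candidates(
    matrix: CooccurrenceMatrix,
    seed_set: Iterable,
    method: str = "ebc",
    counts: CoclusterCounts | None = None,
    tie_seed: int = 0,
    lsa_rank: int | None = None,
    candidates: Sequence | None = None,
) -> pd.DataFrame:
    """Score every candidate row against the seed set.

    ``seed_set`` holds row labels (or integer indices); candidates default
    to all non-seed rows, excluded from the table before normalization.
    Returns a DataFrame with columns label, score, relative_certainty,
    method, sorted by descending score.
    """
    seed_list = list(seed_set)
    if not seed_list:
        raise ValueError("seed set must be non-empty")
    if all(isinstance(s, (int, np.integer)) for s in seed_list):
        S_idx = np.asarray(seed_list, dtype=np.intp)
    else:
        S_idx = matrix.row_indices(seed_list)
    if candidates is None:
        cand_idx = np.setdiff1d(np.arange(matrix.n), S_idx)
    else:
        cand_idx = (np.asarray(candidates, dtype=np.intp)
                    if all(isinstance(c, (int, np.integer)) for c in candidates)
                    else matrix.row_indices(candidates))

    if method == "ebc":
        if counts is None:
            raise ValueError("method 'ebc' needs co-clustering counts")
        scores = [ebc_score(counts, S_idx, int(t), tie_seed) for t in cand_idx]
    elif method == "avgcos":
        scores = [avg_cosine_score(matrix, S_idx, int(t)) for t in cand_idx]
    elif method == "ranksum":
        scores = [ranksum_cosine_score(matrix, S_idx, int(t), tie_seed) for t in cand_idx]
    elif method in ("lsa_avgcos", "lsa_ranksum"):
        if lsa_rank is None:
            raise ValueError("LSA methods need lsa_rank")
        E = lsa_embed(matrix, lsa_rank)
        if method == "lsa_avgcos":
            scores = [avg_cosine_score(E, S_idx, int(t)) for t in cand_idx]
        else:
            scores = [ranksum_cosine_score(E, S_idx, int(t), tie_seed) for t in cand_idx]
    else:
        raise ValueError(f"unknown method {method!r}")

    table = pd.DataFrame(
        {
            "label": [matrix.row_labels[i] for i in cand_idx],
            "score": scores,
            "relative_certainty": relative_certainty(scores),
            "method": method,
        }
    )
    return table.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
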