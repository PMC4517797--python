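"""Benchmarking protocol for seeded relationship ranking.

For each seed-set size, many replicate (seed set, test set) draws are made;
every scoring method ranks the same test set with the same seed set (the
draws are paired across methods), the ranking quality is summarized by the
area under the ROC curve, and the headline metric is the fraction of
replicates with AUC strictly above a threshold (0.7 by default). A test set
holds a fixed number of labeled positives and negatives (50/50 in the
reference protocol) and never overlaps the seed set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .ensemble import CoclusterCounts
from .matrix import CooccurrenceMatrix
from .scoring import score_candidates

__all__ = [
    "BenchmarkConfig",
    "sample_seed_test",
    "auc",
    "replicate_aucs",
    "benchmark",
    "seed_overlap_stats",
]


@dataclass
class BenchmarkConfig:
    """Protocol parameters; defaults follow the reference evaluation."""

    sizes: tuple[int, ...] = (1, 2, 3, 4, 5, 10, 25, 50, 100)
    replicates: int = 1000
    test_positives: int = 50
    test_negatives: int = 50
    auc_threshold: float = 0.7
    master_seed: int = 0


def sample_seed_test(
    positives: Sequence[int],
    negatives: Sequence[int],
    seed_size: int,
    config: BenchmarkConfig,
    rng: np.random.Generator,
    seed_pool: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a seed set and a disjoint labeled test set without replacement.

    Seeds come from ``seed_pool`` when given (e.g. ranking one split of
    positives with seeds from the other), otherwise from ``positives``.
    Returns (seed_indices, test_indices, test_labels).
    """
    positives = np.asarray(positives, dtype=np.intp)
    negatives = np.asarray(negatives, dtype=np.intp)
    pool = positives if seed_pool is None else np.asarray(seed_pool, dtype=np.intp)
    needed_pos = config.test_positives + (seed_size if seed_pool is None else 0)
    if len(positives) < needed_pos:
        raise ValueError(
            f"need >= {needed_pos} positives "
            f"({config.test_positives} test + {seed_size if seed_pool is None else 0} seed), "
            f"have {len(positives)}"
        )
    if seed_pool is not None and len(pool) < seed_size:
        raise ValueError(f"seed pool of {len(pool)} cannot supply {seed_size} seeds")
    if len(negatives) < config.test_negatives:
        raise ValueError(
            f"need >= {config.test_negatives} negatives, have {len(negatives)}"
        )
    S = rng.choice(pool, size=seed_size, replace=False)
    remaining = np.setdiff1d(positives, S)
    test_pos = rng.choice(remaining, size=config.test_positives, replace=False)
    test_neg = rng.choice(negatives, size=config.test_negatives, replace=False)
    test = np.concatenate([test_pos, test_neg])
    labels = np.concatenate(
        [np.ones(len(test_pos), dtype=int), np.zeros(len(test_neg), dtype=int)]
    )
    return S, test, labels


def auc(scores, labels) -> float:
    """Area under the ROC curve: P(random positive ranked above random
    negative), ties credited 0.5. Requires both classes present."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both positive and negative labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _score_test_items(matrix, counts, S, test, method, tie_seed, lsa_rank):
    if method == "random":
        # pure-noise null scorer: uniform scores, seeded per replicate
        return np.random.default_rng([tie_seed, len(test)]).random(len(test))
    table = score_candidates(
        matrix, S.tolist(), method=method, counts=counts,
        tie_seed=tie_seed, lsa_rank=lsa_rank, candidates=test.tolist(),
    )
    by_label = dict(zip(table["label"], table["score"]))
    return np.array([by_label[matrix.row_labels[i]] for i in test], dtype=float)


def replicate_aucs(
    matrix: CooccurrenceMatrix,
    counts: CoclusterCounts | None,
    positives,
    negatives,
    config: BenchmarkConfig,
    methods: Sequence[str] = ("ebc", "avgcos", "ranksum"),
    seed_pool=None,
    lsa_rank: int | None = None,
) -> pd.DataFrame:
    """Per-replicate AUCs, paired across methods.

    Each (size, replicate) pair derives its generator from
    (master_seed, size, replicate), so every method scores the identical
    seed and test sets and reruns are exact.
    """
    def to_idx(labels):
        labels = list(labels)
        if all(isinstance(x, (int, np.integer)) for x in labels):
            return np.asarray(labels, dtype=np.intp)
        return matrix.row_indices(labels)

    pos_idx = to_idx(positives)
    neg_idx = to_idx(negatives)
    pool_idx = to_idx(seed_pool) if seed_pool is not None else None
    records = []
    for size in config.sizes:
        for rep in range(config.replicates):
            rng = np.random.default_rng([config.master_seed, size, rep])
            tie_seed = int(rng.integers(0, 2**31 - 1))
            S, test, labels = sample_seed_test(
                pos_idx, neg_idx, size, config, rng, seed_pool=pool_idx
            )
            for method in methods:
                scores = _score_test_items(
                    matrix, counts, S, test, method, tie_seed, lsa_rank
                )
                records.append(
                    {"method": method, "seed_size": size, "replicate": rep,
                     "auc": auc(scores, labels)}
                )
    return pd.DataFrame.from_records(records)


def benchmark(
    matrix: CooccurrenceMatrix,
    counts: CoclusterCounts | None,
    positives,
    negatives,
    config: BenchmarkConfig,
    methods: Sequence[str] = ("ebc", "avgcos", "ranksum"),
    seed_pool=None,
    lsa_rank: int | None = None,
) -> pd.DataFrame:
    """Fraction of replicates with AUC strictly above the threshold.

    Returns a DataFrame with one row per (method, seed size): the
    above-threshold fraction and the median AUC.
    """
    aucs = replicate_aucs(
        matrix, counts, positives, negatives, config, methods=methods,
        seed_pool=seed_pool, lsa_rank=lsa_rank,
    )
    thr = config.auc_threshold
    out = (
        aucs.groupby(["method", "seed_size"])["auc"]
        .agg(frac_auc_above=lambda a: float(np.mean(a > thr)), median_auc="median")
        .reset_index()
    )
    return out


def synonymy_benchmark(
    n_replicates: int = 25,
    seed: int = 0,
    seed_size: int = 10,
    k: int = 3,
    l: int = 3,
    n_runs: int = 200,
    test_positives: int = 30,
    test_negatives: int = 30,
    methods: Sequence[str] = ("ebc", "avgcos", "ranksum"),
    **scenario_kwargs,
) -> pd.DataFrame:
    """Per-replicate AUCs on the synthetic synonymy scenario.

    Each replicate is a full simulation: a fresh scenario matrix, a fresh
    ITCC ensemble (k × l, N = ``n_runs``), one draw of ``seed_size`` seeds
    from split A, and a test set of split-B positives versus labeled
    negatives scored by every method on identical draws. All randomness
    derives from ``seed``. Returns a DataFrame (method, replicate, auc).
    """
    from .ensemble import run_ensemble
    from .synthetic import synonymy_scenario

    records = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        mseed = int(rng.integers(0, 2**31 - 1))
        eseed = int(rng.integers(0, 2**31 - 1))
        tie_seed = int(rng.integers(0, 2**31 - 1))
        data = synonymy_scenario(seed=mseed, **scenario_kwargs)
        matrix = data.matrix
        counts = run_ensemble(matrix, k, l, n_runs, base_seed=eseed)
        config = BenchmarkConfig(
            sizes=(seed_size,), replicates=1,
            test_positives=test_positives, test_negatives=test_negatives,
        )
        S, test, labels = sample_seed_test(
            matrix.row_indices(data.split_b),
            matrix.row_indices(data.negatives),
            seed_size, config, rng,
            seed_pool=matrix.row_indices(data.split_a),
        )
        for method in methods:
            scores = _score_test_items(matrix, counts, S, test, method,
                                       tie_seed, None)
            records.append({"method": method, "replicate": rep,
                            "auc": auc(scores, labels)})
    return pd.DataFrame.from_records(records)


def seed_overlap_stats(total_pairs: int, n_class_a: int, n_class_b: int,
                       n_shared: int) -> dict:
    """Bookkeeping over two labeled seed classes within one dataset.

    Returns the count of pairs known to neither class and the percentage
    overlap of the two classes (shared / union, one decimal).
    """
    if n_shared > min(n_class_a, n_class_b):
        raise ValueError("shared count exceeds a class size")
    union = n_class_a + n_class_b - n_shared
    if union > total_pairs:
        raise ValueError("labeled union exceeds the dataset size")
    return {
        "known_to_neither": total_pairs - union,
        "overlap_pct": round(100.0 * n_shared / union, 1),
    }
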