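"""The relationship landscape: correlation distance, minimax-linkage tree.

Two rows with similar relationships rank all other rows similarly by
co-clustering frequency, so the distance between rows i and j is
1 − ρ_ij, where ρ_ij is the Spearman correlation of rows C_i· and C_j· of
the co-clustering count matrix (full rows, diagonal entries included; ties
get average ranks). Agglomerative clustering with minimax linkage — the
merge cost of two groups is the smallest achievable "prototype radius",
the minimum over members p of the maximum distance from p to any member —
turns the distances into a dendrogram whose every internal node carries an
actual row as its prototype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats

from .ensemble import CoclusterCounts

__all__ = [
    "cocluster_distance",
    "LinkageTree",
    "minimax_linkage",
    "cut_tree",
    "cluster_enrichment",
    "compare_cluster_values",
    "to_newick",
]


def cocluster_distance(counts) -> np.ndarray:
    """1 − Spearman ρ over full rows of C; raises on a constant row."""
    C = counts.counts if isinstance(counts, CoclusterCounts) else np.asarray(counts)
    n = C.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows for rank correlation")
    variances = C.var(axis=1)
    if np.any(variances == 0):
        bad = int(np.flatnonzero(variances == 0)[0])
        raise ValueError(f"row {bad} is constant; Spearman correlation undefined")
    rho = stats.spearmanr(C, axis=1).statistic
    rho = np.atleast_2d(rho)
    D = 1.0 - rho
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


@dataclass
class LinkageTree:
    """Minimax-linkage merge tree in scipy linkage layout plus prototypes.

    ``Z`` rows are (left id, right id, height, size); leaves are 0..n-1 and
    merge i creates node n+i. ``prototypes[i]`` is the leaf attaining the
    minimax radius of merge i.
    """

    Z: np.ndarray
    prototypes: np.ndarray
    labels: list

    @property
    def n_leaves(self) -> int:
        return self.Z.shape[0] + 1

    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def cut(self, height: float) -> np.ndarray:
        """Flat clusters after applying every merge of height ≤ ``height``.

        Returns integer cluster ids (1-based, scipy convention), one per leaf.
        """
        if height < 0:
            raise ValueError("cut height must be >= 0")
        return sch.fcluster(self.Z, t=height, criterion="distance")

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "left": self.Z[:, 0].astype(int),
                "right": self.Z[:, 1].astype(int),
                "height": self.Z[:, 2],
                "size": self.Z[:, 3].astype(int),
                "prototype": [self.labels[p] for p in self.prototypes],
            }
        )


def minimax_linkage(D: np.ndarray, labels: Sequence | None = None) -> LinkageTree:
    """Agglomerative clustering under minimax linkage.

    At every step the pair of clusters whose union has the smallest minimax
    radius r(G) = min_{p∈G} max_{q∈G} d(p, q) is merged, and the minimizing
    point is recorded as the merge's prototype. Ties go to the lowest
    (left, right) node-id pair, making the tree deterministic.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if labels is None:
        labels = list(range(n))
    labels = list(labels)

    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    cost: dict[tuple[int, int], tuple[float, int]] = {}

    def pair_cost(a: int, b: int) -> tuple[float, int]:
        u = np.concatenate([members[a], members[b]])
        radii = D[np.ix_(u, u)].max(axis=1)
        j = int(np.argmin(radii))  # lowest index wins ties
        return float(radii[j]), int(u[j])

    active = sorted(members)
    for a_i, a in enumerate(active):
        for b in active[a_i + 1:]:
            cost[(a, b)] = pair_cost(a, b)

    Z = np.zeros((n - 1, 4))
    prototypes = np.zeros(n - 1, dtype=np.intp)
    next_id = n
    for step in range(n - 1):
        (a, b), (h, proto) = min(cost.items(), key=lambda kv: (kv[1][0], kv[0]))
        Z[step] = (a, b, h, len(members[a]) + len(members[b]))
        prototypes[step] = proto
        members[next_id] = np.concatenate([members[a], members[b]])
        del members[a], members[b]
        cost = {k: v for k, v in cost.items() if a not in k and b not in k}
        for other in members:
            if other != next_id:
                key = (other, next_id) if other < next_id else (next_id, other)
                cost[key] = pair_cost(other, next_id)
        next_id += 1
    return LinkageTree(Z=Z, prototypes=prototypes, labels=labels)


def cut_tree(tree: LinkageTree, height: float) -> np.ndarray:
    return tree.cut(height)


def cluster_enrichment(
    assignment: np.ndarray,
    label_sets: Mapping[str, set],
    leaves: Sequence | None = None,
) -> pd.DataFrame:
    """Per-cluster size and percentage of members in each label set.

    ``assignment`` is one cluster id per leaf; ``leaves`` are the leaf
    labels (defaults to positions). Percentages are reported to one decimal.
    """
    assignment = np.asarray(assignment)
    if leaves is None:
        leaves = list(range(len(assignment)))
    leaves = list(leaves)
    rows = []
    for cid in np.unique(assignment):
        in_cluster = [leaves[i] for i in np.flatnonzero(assignment == cid)]
        row = {"cluster": cid, "size": len(in_cluster)}
        for name, labeled in label_sets.items():
            hits = sum(1 for leaf in in_cluster if leaf in labeled)
            row[f"pct_{name}"] = round(100.0 * hits / len(in_cluster), 1)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_cluster_values(values_a, values_b) -> tuple[float, float, float]:
    """Medians of two samples and the two-sided Mann-Whitney p-value.

    The exact null distribution is enumerated when both samples have at
    most 8 observations; the normal approximation (with tie correction)
    is used otherwise.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (a.size <= 8 and b.size <= 8) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(np.median(a)), float(np.median(b)), float(res.pvalue)


def _sanitize(label) -> str:
    if isinstance(label, tuple):
        label = "_".join(str(x) for x in label)
    return str(label).replace(" ", "_").replace(",", "_").replace(";", "_") \
        .replace("(", "_").replace(")", "_").replace(":", "_")


def to_newick(tree: LinkageTree) -> str:
    """Ultrametric Newick string; branch lengths are height differences."""
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    for i, (a, b, h, _) in enumerate(tree.Z):
        heights[n + i] = h

    def render(node: int, parent_height: float) -> str:
        node = int(node)
        branch = parent_height - heights[node]
        if node < n:
            return f"{_sanitize(tree.labels[node])}:{branch:g}"
        a, b = tree.Z[node - n, 0], tree.Z[node - n, 1]
        inner = f"({render(a, heights[node])},{render(b, heights[node])})"
        return f"{inner}:{branch:g}"

    root = n + tree.Z.shape[0] - 1
    a, b = tree.Z[-1, 0], tree.Z[-1, 1]
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"
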