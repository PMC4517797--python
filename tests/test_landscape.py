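import io

import numpy as np
import pytest
from scipy import stats

from ebc.ensemble import CoclusterCounts
from ebc.landscape import (
    cluster_enrichment,
    cocluster_distance,
    compare_cluster_values,
    cut_tree,
    minimax_linkage,
    to_newick,
)


def naive_minimax(D):
    """Independent reference implementation: re-evaluates every candidate
    merge and prototype exhaustively at every step."""
    D = np.asarray(D, float)
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                u = clusters[a] + clusters[b]
                radii = [max(D[p][q] for q in u) for p in u]
                h = min(radii)
                proto = u[int(np.argmin(radii))]
                if best is None or (h, a, b) < (best[0], best[1], best[2]):
                    best = (h, a, b, proto)
        h, a, b, proto = best
        merges.append((a, b, h, proto))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def random_distance_matrix(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 2))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return D


def line_distances():
    pts = np.array([0.0, 1.0, 10.0])
    return np.abs(pts[:, None] - pts[None])


class TestCoclusterDistance:
    def _counts(self, C, n_runs=None):
        C = np.asarray(C)
        n_runs = n_runs or int(C.max())
        return CoclusterCounts(C, n_runs, "rows", [f"r{i}" for i in range(len(C))])

    def test_identical_rank_profiles_have_zero_distance(self):
        C = np.array([[9, 3, 2], [3, 9, 2], [2, 2, 9]])
        D = cocluster_distance(self._counts(C, 9))
        # rows 0 and 1 rank the others identically up to the symmetric swap
        assert D[0, 0] == 0.0
        assert np.allclose(D, D.T)

    def test_matches_rank_then_pearson_brute_force(self):
        rng = np.random.default_rng(3)
        C = rng.integers(0, 20, size=(5, 5))
        C = C + C.T
        np.fill_diagonal(C, 40)
        D = cocluster_distance(self._counts(C, 40))
        for i in range(5):
            for j in range(5):
                ri = stats.rankdata(C[i])
                rj = stats.rankdata(C[j])
                rho = np.corrcoef(ri, rj)[0, 1]
                assert D[i, j] == pytest.approx(1 - rho, abs=1e-10)

    def test_perfectly_reversed_ranks_give_distance_two(self):
        rows = np.array([
            [1, 2, 3, 4, 5],
            [5, 4, 3, 2, 1],
            [1, 3, 2, 5, 4],
            [2, 1, 4, 3, 5],
            [3, 5, 1, 4, 2],
        ])
        rho = stats.spearmanr(rows[0], rows[1]).statistic
        assert rho == pytest.approx(-1)
        D = 1 - stats.spearmanr(rows, axis=1).statistic
        assert D[0, 1] == pytest.approx(2.0)
        assert np.max(D) <= 2.0 + 1e-12

    def test_constant_row_rejected_by_name(self):
        C = np.array([[5, 5, 5], [5, 5, 1], [5, 1, 5]])
        with pytest.raises(ValueError, match="row 0"):
            cocluster_distance(self._counts(C, 5))

    def test_small_matrices_rejected(self):
        with pytest.raises(ValueError):
            cocluster_distance(self._counts(np.array([[2, 1], [1, 2]]), 2))


class TestMinimaxLinkage:
    def test_two_leaves(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        tree = minimax_linkage(D, labels=["A", "B"])
        assert tree.Z.shape == (1, 4)
        assert tree.Z[0, 2] == 3.0
        assert tree.prototypes[0] in (0, 1)

    def test_line_example_heights_and_prototype(self):
        tree = minimax_linkage(line_distances())
        assert tree.Z[0, 2] == 1.0  # {0, 1} merge
        assert tree.Z[1, 2] == 9.0  # adding the far point; prototype = middle
        assert tree.prototypes[1] == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_reference_on_random_points(self, seed):
        D = random_distance_matrix(7, seed)
        tree = minimax_linkage(D)
        reference = naive_minimax(D)
        for row, proto, (a, b, h, rproto) in zip(tree.Z, tree.prototypes, reference):
            assert (int(row[0]), int(row[1])) == (a, b)
            assert row[2] == pytest.approx(h, abs=1e-12)
            assert proto == rproto

    @pytest.mark.parametrize("seed", range(4))
    def test_heights_non_decreasing(self, seed):
        D = random_distance_matrix(9, seed + 50)
        tree = minimax_linkage(D)
        heights = tree.heights()
        assert np.all(np.diff(heights) >= -1e-12)

    def test_prototype_radius_is_minimal(self):
        D = random_distance_matrix(8, 99)
        tree = minimax_linkage(D)
        n = tree.n_leaves
        members = {i: [i] for i in range(n)}
        for i, (a, b, h, _) in enumerate(tree.Z):
            u = members[int(a)] + members[int(b)]
            members[n + i] = u
            radii = {p: max(D[p][q] for q in u) for p in u}
            proto = tree.prototypes[i]
            assert radii[proto] == pytest.approx(min(radii.values()), abs=1e-12)


class TestCutTree:
    def test_extreme_heights(self):
        D = random_distance_matrix(6, 1)
        tree = minimax_linkage(D)
        assert len(set(tree.cut(tree.Z[-1, 2] + 1))) == 1
        assert len(set(tree.cut(0.0))) == 6

    def test_line_example_cut(self):
        tree = minimax_linkage(line_distances())
        assignment = cut_tree(tree, 5.0)
        assert assignment[0] == assignment[1]
        assert assignment[2] != assignment[0]

    def test_every_cluster_count_reachable_with_distinct_heights(self):
        D = random_distance_matrix(7, 8)
        tree = minimax_linkage(D)
        heights = tree.heights()
        assert len(set(heights)) == len(heights)
        sizes = {len(set(tree.cut(h))) for h in heights}
        sizes.add(len(set(tree.cut(heights[0] / 2))))
        assert sizes == set(range(1, 8))


class TestEnrichment:
    def test_percentages(self):
        assignment = np.array([1, 1, 1, 1, 2, 2])
        leaves = ["a", "b", "c", "d", "e", "f"]
        table = cluster_enrichment(
            assignment, {"pgx": {"a"}, "target": set()}, leaves=leaves
        )
        row1 = table[table.cluster == 1].iloc[0]
        assert row1["size"] == 4
        assert row1["pct_pgx"] == 25.0
        assert row1["pct_target"] == 0.0


class TestClusterComparison:
    def test_identical_samples_give_p_near_one(self):
        _, _, p = compare_cluster_values([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_exact_enumeration_example(self):
        med_a, med_b, p = compare_cluster_values([1, 2, 3], [10, 11, 12])
        assert (med_a, med_b) == (2.0, 11.0)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_medians_match_direct_sorting(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(9), rng.random(14)
        med_a, med_b, _ = compare_cluster_values(a, b)
        assert med_a == np.median(a)
        assert med_b == np.median(b)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_cluster_values([], [1])


class TestNewick:
    def test_two_leaf_convention(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        tree = minimax_linkage(D, labels=["A", "B"])
        assert to_newick(tree) == "(A:1,B:1);"

    def test_line_example_branch_lengths(self):
        tree = minimax_linkage(line_distances(), labels=["x", "y", "z"])
        nwk = to_newick(tree)
        assert nwk == "(z:9,(x:1,y:1):8);"

    def test_round_trip_preserves_leaf_set(self):
        from Bio import Phylo

        D = random_distance_matrix(6, 12)
        labels = [f"leaf {i}" for i in range(6)]
        tree = minimax_linkage(D, labels=labels)
        parsed = Phylo.read(io.StringIO(to_newick(tree)), "newick")
        names = {t.name for t in parsed.get_terminals()}
        assert names == {f"leaf_{i}" for i in range(6)}
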