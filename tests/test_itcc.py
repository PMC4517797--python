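import itertools

import numpy as np
import pytest

from ebc.itcc import (
    ITCC,
    PRESET_KL,
    choose_kl,
    compute_q,
    itcc_run,
    kl_objective,
    normalize_joint,
    smoothed_matrix,
)

from conftest import make_matrix, random_binary_matrix


def brute_force_objective(joint, row_assign, col_assign, k, l):
    """Independent term-by-term evaluation of KL(p || q)."""
    p = joint.p.toarray()
    q = compute_q(joint, np.asarray(row_assign), np.asarray(col_assign), k, l)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                if q[i, j] <= 0:
                    return float("inf")
                total += p[i, j] * np.log(p[i, j] / q[i, j])
    return total


class TestJoint:
    def test_uniform_mass_over_nonzeros(self):
        joint = normalize_joint(make_matrix([[1, 1], [0, 1]]))
        p = joint.p.toarray()
        assert np.allclose(p[p > 0], 1 / 3)

    def test_single_entry_gets_all_mass(self):
        joint = normalize_joint(make_matrix([[1]]))
        assert joint.p.toarray()[0, 0] == 1.0

    def test_marginals_match_independent_summation(self):
        M = random_binary_matrix(10, 10, 0.35, seed=2)
        joint = normalize_joint(make_matrix(M))
        assert abs(joint.p.sum() - 1) < 1e-12
        np.testing.assert_allclose(joint.py, M.sum(axis=1) / M.sum())
        np.testing.assert_allclose(joint.px, M.sum(axis=0) / M.sum())


class TestComputeQ:
    def test_singleton_clusters_reproduce_p(self):
        M = random_binary_matrix(5, 4, 0.5, seed=1)
        joint = normalize_joint(make_matrix(M))
        q = compute_q(joint, np.arange(5), np.arange(4), 5, 4)
        np.testing.assert_allclose(q, joint.p.toarray(), atol=1e-14)

    def test_single_cluster_gives_independence(self):
        M = random_binary_matrix(6, 5, 0.4, seed=4)
        joint = normalize_joint(make_matrix(M))
        q = compute_q(joint, np.zeros(6, int), np.zeros(5, int), 1, 1)
        np.testing.assert_allclose(q, np.outer(joint.py, joint.px), atol=1e-14)

    def test_hand_expanded_factorization_3x3(self):
        # 2+1 / 2+1 assignment evaluated by expanding the three factors
        joint = normalize_joint(make_matrix([[1, 1, 0], [1, 0, 1], [0, 1, 1]]))
        ra, ca = np.array([0, 0, 1]), np.array([0, 0, 1])
        q = compute_q(joint, ra, ca, 2, 2)
        p = joint.p.toarray()
        for i in range(3):
            for j in range(3):
                block = p[np.ix_(ra == ra[i], ca == ca[j])].sum()
                expected = (
                    block
                    * (joint.px[j] / joint.px[ca == ca[j]].sum())
                    * (joint.py[i] / joint.py[ra == ra[i]].sum())
                )
                assert q[i, j] == pytest.approx(expected, abs=1e-14)

    def test_marginals_preserved_for_any_assignment(self):
        M = random_binary_matrix(8, 6, 0.4, seed=7)
        joint = normalize_joint(make_matrix(M))
        rng = np.random.default_rng(0)
        for _ in range(5):
            ra = rng.integers(0, 3, 8)
            ca = rng.integers(0, 2, 6)
            q = compute_q(joint, ra, ca, 3, 2)
            np.testing.assert_allclose(q.sum(axis=1), joint.py, atol=1e-12)
            np.testing.assert_allclose(q.sum(axis=0), joint.px, atol=1e-12)
            assert abs(q.sum() - 1) < 1e-12


class TestKLObjective:
    def test_zero_when_q_equals_p(self):
        joint = normalize_joint(make_matrix([[1, 0], [0, 1]]))
        assert kl_objective(joint, joint.p.toarray()) == 0.0

    def test_uniform_diagonal_collapsed_to_one_cluster_is_ln2(self, diagonal_2x2):
        joint = normalize_joint(diagonal_2x2)
        q = compute_q(joint, np.zeros(2, int), np.zeros(2, int), 1, 1)
        assert kl_objective(joint, q) == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_brute_force_sum(self):
        M = random_binary_matrix(6, 6, 0.45, seed=11)
        joint = normalize_joint(make_matrix(M))
        rng = np.random.default_rng(1)
        ra, ca = rng.integers(0, 2, 6), rng.integers(0, 3, 6)
        q = compute_q(joint, ra, ca, 2, 3)
        assert kl_objective(joint, q) == pytest.approx(
            brute_force_objective(joint, ra, ca, 2, 3), abs=1e-12
        )


class TestITCCRun:
    def test_perfect_blocks_reached_with_restarts(self, block_diagonal_4x4):
        results = [itcc_run(block_diagonal_4x4, 2, 2, seed=s) for s in range(20)]
        best = min(results, key=lambda r: r.objective)
        assert best.objective == pytest.approx(0.0, abs=1e-12)
        ra = best.row_assign
        assert ra[0] == ra[1] and ra[2] == ra[3] and ra[0] != ra[2]

    def test_best_restart_reaches_enumerated_global_optimum(self):
        M = random_binary_matrix(4, 4, 0.5, seed=13)
        mat = make_matrix(M)
        joint = normalize_joint(mat)
        global_best = min(
            brute_force_objective(joint, ra, ca, 2, 2)
            for ra in itertools.product(range(2), repeat=4)
            for ca in itertools.product(range(2), repeat=4)
        )
        best = min(itcc_run(mat, 2, 2, seed=s).objective for s in range(20))
        assert best == pytest.approx(global_best, abs=1e-10)

    def test_objective_trace_is_monotone(self):
        M = random_binary_matrix(10, 10, 0.3, seed=17)
        res = itcc_run(make_matrix(M), 3, 3, seed=5)
        assert np.all(np.diff(res.trace) <= 1e-12)

    def test_same_seed_reproduces_bit_identical_result(self):
        M = random_binary_matrix(12, 9, 0.3, seed=19)
        mat = make_matrix(M)
        r1 = itcc_run(mat, 3, 3, seed=42)
        r2 = itcc_run(mat, 3, 3, seed=42)
        assert np.array_equal(r1.row_assign, r2.row_assign)
        assert np.array_equal(r1.col_assign, r2.col_assign)
        assert r1.objective == r2.objective

    def test_analytic_limits(self, diagonal_2x2):
        assert itcc_run(diagonal_2x2, 2, 2, seed=0).objective == pytest.approx(0, abs=1e-12)
        res = itcc_run(diagonal_2x2, 1, 1, seed=0)
        assert res.objective == pytest.approx(np.log(2), abs=1e-12)
        model = ITCC(diagonal_2x2, 1, 1)
        assert res.objective == pytest.approx(model.mutual_information, abs=1e-12)

    def test_cluster_number_bounds_checked(self, diagonal_2x2):
        with pytest.raises(ValueError):
            ITCC(diagonal_2x2, 0, 1)
        with pytest.raises(ValueError):
            ITCC(diagonal_2x2, 1, 3)

    def test_summary_mentions_objective(self, block_diagonal_4x4):
        res = itcc_run(block_diagonal_4x4, 2, 2, seed=3)
        assert "KL(p||q)" in res.summary()


class TestSmoothing:
    def test_perfect_blocks_reproduce_original(self, block_diagonal_4x4):
        best = min(
            (itcc_run(block_diagonal_4x4, 2, 2, seed=s) for s in range(20)),
            key=lambda r: r.objective,
        )
        np.testing.assert_allclose(
            smoothed_matrix(block_diagonal_4x4, best),
            block_diagonal_4x4.toarray(),
            atol=1e-10,
        )

    def test_row_sums_preserved(self):
        M = random_binary_matrix(8, 6, 0.4, seed=23)
        mat = make_matrix(M)
        res = itcc_run(mat, 3, 2, seed=1)
        smoothed = smoothed_matrix(mat, res)
        np.testing.assert_allclose(smoothed.sum(axis=1), M.sum(axis=1), atol=1e-9)
        np.testing.assert_allclose(smoothed.sum(axis=0), M.sum(axis=0), atol=1e-9)

    def test_wrong_matrix_rejected(self, block_diagonal_4x4, diagonal_2x2):
        res = itcc_run(block_diagonal_4x4, 2, 2, seed=0)
        with pytest.raises(ValueError):
            smoothed_matrix(diagonal_2x2, res)


class TestChooseKL:
    def test_perfect_two_block_structure_selects_2_2(self, block_diagonal_4x4):
        k, l = choose_kl(block_diagonal_4x4, [1, 2, 3], [1, 2, 3],
                         restarts=8, seed=0)
        assert (k, l) == (2, 2)

    def test_single_candidate_grid(self, diagonal_2x2):
        assert choose_kl(diagonal_2x2, [2], [2], restarts=2, seed=0) == (2, 2)

    def test_empty_grid_rejected(self, diagonal_2x2):
        with pytest.raises(ValueError):
            choose_kl(diagonal_2x2, [], [1], restarts=1, seed=0)

    def test_published_presets_exposed(self):
        assert PRESET_KL["dense"] == (30, 125)
        assert PRESET_KL["sparse"] == (7, 25)
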