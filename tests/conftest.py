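import numpy as np
import pytest
import scipy.sparse as sp

from ebc.matrix import CooccurrenceMatrix


def make_matrix(M, prefix="r"):
    """Wrap a dense 0/1 array in a CooccurrenceMatrix with generated labels."""
    M = np.asarray(M)
    n, m = M.shape
    return CooccurrenceMatrix(
        sp.csr_matrix(M),
        [(f"drug{i:03d}", f"gene{i:03d}") for i in range(n)],
        [f"path{j:03d}" for j in range(m)],
    )


def random_binary_matrix(n, m, density, seed):
    """Random binary matrix with no empty rows/columns."""
    rng = np.random.default_rng(seed)
    M = (rng.random((n, m)) < density).astype(np.int8)
    for i in np.flatnonzero(M.sum(axis=1) == 0):
        M[i, rng.integers(0, m)] = 1
    for j in np.flatnonzero(M.sum(axis=0) == 0):
        M[rng.integers(0, n), j] = 1
    return M


@pytest.fixture
def block_diagonal_4x4():
    """Two perfect 2×2 blocks on the diagonal."""
    return make_matrix(
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]]
    )


@pytest.fixture
def diagonal_2x2():
    """Uniform mass on the diagonal: I(X;Y) = ln 2."""
    return make_matrix(np.eye(2, dtype=int))
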