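"""Information-theoretic co-clustering (ITCC).

The binary co-occurrence matrix is treated as an empirical joint probability
distribution p(x, y) over its columns X (dependency paths) and rows Y
(drug-gene pairs). Given k row clusters and l column clusters, ITCC seeks
assignments minimizing KL(p || q) where q is the block factorization

    q(x, y) = q(x̂, ŷ) · q(x | x̂) · q(y | ŷ),

with q(x|x̂) = p(x)/p(x̂) and q(y|ŷ) = p(y)/p(ŷ). Because q preserves the
row and column marginals of p as well as all block masses, the objective
equals the mutual-information gap I(X;Y) − I(X̂;Ŷ), which is how the fitting
loop evaluates it; the direct term-by-term sum is kept in
:func:`kl_objective` as an independent formulation.

Minimization alternates a batch row step (each row moves to the row cluster
ŷ minimizing KL(p(X|y) || q(X|ŷ))) and the symmetric column step; each step
is guaranteed not to increase the objective. Cluster assignments are
initialized uniformly at random from the run's seeded generator, so
different seeds converge to different local optima — the diversity the
ensemble stage relies on.

All divergences are in nats (natural log).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .matrix import CooccurrenceMatrix

__all__ = [
    "JointDistribution",
    "ITCC",
    "ITCCResults",
    "normalize_joint",
    "compute_q",
    "kl_objective",
    "itcc_run",
    "smoothed_matrix",
    "choose_kl",
    "PRESET_KL",
]

#: Published optimal cluster numbers for the two dataset presets.
PRESET_KL = {"dense": (30, 125), "sparse": (7, 25)}

_MASS_TOL = 1e-12


@dataclass(frozen=True)
class JointDistribution:
    """Empirical joint p(x, y) with marginals; rows are Y, columns are X."""

    p: sp.csr_matrix  # n×m, float64, sums to 1
    py: np.ndarray  # row marginals p(y), length n
    px: np.ndarray  # column marginals p(x), length m
    total: float  # original total count (for rescaling smoothed output)

    def __post_init__(self):
        if abs(self.p.sum() - 1.0) > _MASS_TOL:
            raise ValueError("joint mass does not sum to 1")


def normalize_joint(matrix: CooccurrenceMatrix) -> JointDistribution:
    """p(x, y) = M_yx / ΣM. Requires at least one nonzero entry."""
    total = float(matrix.data.sum())
    if total <= 0:
        raise ValueError("matrix has no nonzero entries")
    p = sp.csr_matrix(matrix.data, dtype=np.float64) / total
    py = np.asarray(p.sum(axis=1)).ravel()
    px = np.asarray(p.sum(axis=0)).ravel()
    return JointDistribution(p=p, py=py, px=px, total=total)


def _block_masses(joint, row_assign, col_assign, k, l) -> np.ndarray:
    """q(x̂, ŷ) as a k×l array of block mass sums."""
    coo = joint.p.tocoo()
    Q = np.zeros((k, l))
    np.add.at(Q, (row_assign[coo.row], col_assign[coo.col]), coo.data)
    return Q


def compute_q(
    joint: JointDistribution,
    row_assign: np.ndarray,
    col_assign: np.ndarray,
    k: int,
    l: int,
) -> np.ndarray:
    """Dense block-factorized approximation q(x, y) as an n×m array.

    An empty cluster has block mass 0 and its conditionals are defined as 0.
    """
    row_assign = np.asarray(row_assign)
    col_assign = np.asarray(col_assign)
    Q = _block_masses(joint, row_assign, col_assign, k, l)
    pyh = np.bincount(row_assign, weights=joint.py, minlength=k)
    pxh = np.bincount(col_assign, weights=joint.px, minlength=l)
    with np.errstate(divide="ignore", invalid="ignore"):
        ry = np.where(pyh[row_assign] > 0, joint.py / pyh[row_assign], 0.0)
        cx = np.where(pxh[col_assign] > 0, joint.px / pxh[col_assign], 0.0)
    return Q[np.ix_(row_assign, col_assign)] * np.outer(ry, cx)


def kl_objective(p, q) -> float:
    """Σ p·ln(p/q) with the 0·ln(0/·)=0 convention; +inf if q=0 where p>0.

    ``p`` may be a JointDistribution, a sparse matrix or a dense array; ``q``
    a dense array of the same shape.
    """
    if isinstance(p, JointDistribution):
        p = p.p
    if sp.issparse(p):
        p = p.toarray()
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    if np.any(q[mask] <= 0):
        return float("inf")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _mutual_information(P: np.ndarray, rowm: np.ndarray, colm: np.ndarray) -> float:
    """I from a dense joint table and its marginals (0 log 0 = 0)."""
    outer = np.outer(rowm, colm)
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / outer[mask])))


class ITCC:
    """Information-theoretic co-clustering model for one co-occurrence matrix.

    Parameters
    ----------
    matrix : CooccurrenceMatrix
    k, l : int
        Number of row clusters (1..n) and column clusters (1..m).
    max_iter : int
        Maximum full row+column sweeps (default 50).
    tol : float
        Relative objective decrease below which a sweep stops iteration.
    """

    def __init__(self, matrix: CooccurrenceMatrix, k: int, l: int,
                 max_iter: int = 50, tol: float = 1e-6):
        if not (1 <= k <= matrix.n):
            raise ValueError(f"k={k} out of range [1, {matrix.n}]")
        if not (1 <= l <= matrix.m):
            raise ValueError(f"l={l} out of range [1, {matrix.m}]")
        self.matrix = matrix
        self.k = int(k)
        self.l = int(l)
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.joint = normalize_joint(matrix)
        self._ifull = _mutual_information(
            self.joint.p.toarray(), self.joint.py, self.joint.px
        ) if matrix.n * matrix.m <= 4_000_000 else None
        # Sparse fallback for very large matrices: compute I(X;Y) from nonzeros.
        if self._ifull is None:
            coo = self.joint.p.tocoo()
            vals = coo.data
            self._ifull = float(
                np.sum(vals * np.log(vals / (self.joint.py[coo.row] * self.joint.px[coo.col])))
            )

    @property
    def mutual_information(self) -> float:
        """I(X;Y) of the empirical joint, in nats."""
        return self._ifull

    # -- fitting -----------------------------------------------------------
    def fit(self, seed: int = 0) -> "ITCCResults":
        rng = np.random.default_rng(seed)
        n, m, k, l = self.matrix.n, self.matrix.m, self.k, self.l
        joint = self.joint
        p = joint.p
        pT = p.T.tocsr()

        def center_init(V, groups):
            # Random cluster centers: pick `groups` distinct items, assign
            # every item to its most cosine-similar center (ties: lowest
            # center index). Each center belongs to its own cluster, so no
            # cluster starts empty and k=n yields the singleton clustering.
            size = V.shape[0]
            centers = rng.choice(size, size=groups, replace=False)
            norms = np.sqrt(np.asarray(V.multiply(V).sum(axis=1)).ravel())
            sims = np.asarray((V @ V[centers].T).todense()) / (
                np.outer(norms, norms[centers]) + 1e-300
            )
            # Random tie-breaks: items equally similar to several centers
            # (e.g. zero overlap with all of them) scatter instead of all
            # falling into the first cluster.
            sims += rng.random(sims.shape) * 1e-9
            assign = np.argmax(sims, axis=1)
            assign[centers] = np.arange(groups)
            return assign

        row_assign = center_init(p, k)
        col_assign = center_init(pT, l)

        # Row-aggregated and column-aggregated joints, refreshed lazily.
        def col_agg(ca):  # n×l: mass of row y in column cluster x̂
            ind = sp.csr_matrix(
                (np.ones(m), (np.arange(m), ca)), shape=(m, l)
            )
            return np.asarray((p @ ind).todense())

        def row_agg(ra):  # m×k: mass of column x in row cluster ŷ
            ind = sp.csr_matrix(
                (np.ones(n), (np.arange(n), ra)), shape=(n, k)
            )
            return np.asarray((pT @ ind).todense())

        def objective(ra, ca):
            Q = _block_masses(joint, ra, ca, k, l)
            pyh = np.bincount(ra, weights=joint.py, minlength=k)
            pxh = np.bincount(ca, weights=joint.px, minlength=l)
            return max(self._ifull - _mutual_information(Q, pyh, pxh), 0.0)

        def reassign(agg, cluster_cond_log, invalid, current):
            """Batch argmin step shared by rows and columns.

            agg : items×groups mass table p(group | item)·p(item)
            cluster_cond_log : candidates×groups log q(group | candidate)
            invalid : candidates×groups True where q is 0
            current : current assignment (kept when every candidate diverges)
            """
            D = -(agg @ cluster_cond_log.T)
            bad = (agg > 0).astype(float) @ invalid.T.astype(float)
            D[bad > 0] = np.inf
            new = np.argmin(D, axis=1)  # lowest index wins ties
            allinf = ~np.isfinite(D[np.arange(D.shape[0]), new])
            new[allinf] = current[allinf]
            return new

        trace = [objective(row_assign, col_assign)]
        n_sweeps = 0
        converged = False
        for sweep in range(self.max_iter):
            # Row step: reassign rows given column clusters.
            Q = _block_masses(joint, row_assign, col_assign, k, l)
            pyh = np.bincount(row_assign, weights=joint.py, minlength=k)
            with np.errstate(divide="ignore", invalid="ignore"):
                cond = np.where(pyh[:, None] > 0, Q / pyh[:, None], 0.0)
            invalid = cond <= 0
            logcond = np.where(invalid, 0.0, np.log(np.where(invalid, 1.0, cond)))
            row_assign = reassign(col_agg(col_assign), logcond, invalid, row_assign)
            trace.append(objective(row_assign, col_assign))

            # Column step: reassign columns given row clusters.
            Q = _block_masses(joint, row_assign, col_assign, k, l)
            pxh = np.bincount(col_assign, weights=joint.px, minlength=l)
            with np.errstate(divide="ignore", invalid="ignore"):
                cond = np.where(pxh[None, :] > 0, Q / pxh[None, :], 0.0)  # k×l
            condT = cond.T  # l×k: q(ŷ | x̂ = candidate)
            invalid = condT <= 0
            logcond = np.where(invalid, 0.0, np.log(np.where(invalid, 1.0, condT)))
            col_assign = reassign(row_agg(row_assign), logcond, invalid, col_assign)
            trace.append(objective(row_assign, col_assign))

            n_sweeps = sweep + 1
            prev, cur = trace[-3], trace[-1]
            if prev - cur <= self.tol * max(prev, 1e-300):
                converged = True
                break

        return ITCCResults(
            model=self,
            row_assign=np.asarray(row_assign, dtype=np.intp),
            col_assign=np.asarray(col_assign, dtype=np.intp),
            objective=trace[-1],
            trace=np.asarray(trace),
            n_iter=n_sweeps,
            seed=seed,
            converged=converged,
        )


@dataclass
class ITCCResults:
    """One converged biclustering: assignments, objective and its trace."""

    model: ITCC
    row_assign: np.ndarray
    col_assign: np.ndarray
    objective: float
    trace: np.ndarray
    n_iter: int
    seed: int
    converged: bool

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def l(self) -> int:
        return self.model.l

    def q(self) -> np.ndarray:
        """Dense block-factorized approximation q(x, y)."""
        return compute_q(self.model.joint, self.row_assign, self.col_assign,
                         self.k, self.l)

    def smoothed(self) -> np.ndarray:
        """q rescaled to the original matrix total: fills in unobserved cells."""
        return self.q() * self.model.joint.total

    def summary(self) -> str:
        lines = [
            "ITCC biclustering results",
            "=" * 34,
            f"matrix            {self.model.matrix.n} x {self.model.matrix.m}",
            f"row clusters (k)  {self.k}",
            f"col clusters (l)  {self.l}",
            f"seed              {self.seed}",
            f"sweeps            {self.n_iter} ({'converged' if self.converged else 'max_iter reached'})",
            f"KL(p||q) [nats]   {self.objective:.6f}",
            f"I(X;Y) [nats]     {self.model.mutual_information:.6f}",
            f"info captured     {100 * (1 - self.objective / self.model.mutual_information):.1f}%"
            if self.model.mutual_information > 0 else "info captured     n/a",
        ]
        return "\n".join(lines)


def itcc_run(matrix: CooccurrenceMatrix, k: int, l: int, seed: int = 0,
             max_iter: int = 50, tol: float = 1e-6) -> ITCCResults:
    """Functional wrapper: one seeded ITCC run."""
    return ITCC(matrix, k, l, max_iter=max_iter, tol=tol).fit(seed)


def smoothed_matrix(matrix: CooccurrenceMatrix, results: ITCCResults) -> np.ndarray:
    if results.model.matrix is not matrix:
        raise ValueError("biclustering was fitted on a different matrix")
    return results.smoothed()


def choose_kl(
    matrix: CooccurrenceMatrix,
    k_grid: Sequence[int],
    l_grid: Sequence[int],
    restarts: int = 5,
    seed: int = 0,
    penalty: float = 0.1,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[int, int]:
    """Grid selection of (k, l) by penalized best-of-restarts objective.

    Score(k, l) = min over restarts of KL(p||q) + penalty·(k+l)/min(n, m).
    The penalty breaks the flat region where larger grids also reach the
    same objective. Deterministic given ``seed``; ties go to the first grid
    point in (k, l) iteration order.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    l_grid = sorted(set(int(l) for l in l_grid))
    if not k_grid or not l_grid:
        raise ValueError("empty k or l grid")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=(len(k_grid) * len(l_grid), restarts))
    best, best_kl = None, None
    idx = 0
    scale = min(matrix.n, matrix.m)
    for k in k_grid:
        for l in l_grid:
            model = ITCC(matrix, k, l, max_iter=max_iter, tol=tol)
            obj = min(model.fit(int(s)).objective for s in run_seeds[idx])
            score = obj + penalty * (k + l) / scale
            if best is None or score < best:
                best, best_kl = score, (k, l)
            idx += 1
    return best_kl
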