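"""Consensus non-negative matrix factorization with cophenetic k-selection.

Genes with similar expression patterns are clustered by factorizing the
non-negative expression matrix M (genes x samples) as M ~ Y Z with
non-negative factors of inner dimension k, assigning each gene to its
dominant component of Y.  Because NMF is sensitive to initialization, each k
is run from many random restarts and the co-clustering frequencies are
averaged into a consensus matrix; the cophenetic correlation between the
consensus-derived distances and their average-linkage dendrogram measures
how stable the clustering is.  The number of mathematically stable clusters
is the largest k before the cophenetic coefficient's first sharp drop.

The factorization uses multiplicative updates minimising the generalized
Kullback-Leibler divergence (Frobenius norm available as an option), run for
a fixed iteration count from a seeded random positive initialization so that
results are bitwise reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)

_EPS = 1e-12

__all__ = [
    "PositivityError",
    "NMFFactorization",
    "ConsensusNMF",
    "nmf_factorize",
    "assign_clusters",
    "connectivity_matrix",
    "consensus",
    "cophenetic_coefficient",
    "select_stable_k",
]


class PositivityError(ValueError):
    """The input matrix holds a negative entry (NMF requires M >= 0)."""


@dataclass
class NMFFactorization:
    """Factors M ~ Y Z (Y: genes x k, Z: k x samples) with the objective
    value recorded after every update; the sequence is non-increasing."""

    Y: np.ndarray
    Z: np.ndarray
    objective: np.ndarray
    loss: str

    @property
    def k(self) -> int:
        return self.Y.shape[1]

    def reconstruction(self) -> np.ndarray:
        return self.Y @ self.Z


def _check_nonnegative(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be a 2-D matrix")
    neg = np.argwhere(M < 0)
    if neg.size:
        i, j = neg[0]
        raise PositivityError(
            f"negative entry M[{i}, {j}] = {M[i, j]}; NMF requires only "
            "non-negative values"
        )
    return M


def _kl_divergence(M: np.ndarray, R: np.ndarray) -> float:
    R = np.maximum(R, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(M > 0, M * np.log(M / R) - M + R, R)
    return float(term.sum())


def nmf_factorize(
    M: np.ndarray,
    k: int,
    n_iter: int = 2000,
    seed: int | np.random.Generator | None = None,
    loss: str = "kl",
) -> NMFFactorization:
    """Factorize a non-negative matrix by multiplicative updates.

    Parameters
    ----------
    M : array, shape (R, C)
        Non-negative data matrix (genes x samples); a negative entry raises
        :class:`PositivityError` naming the offending cell.  All-zero rows
        or columns are lifted by a small epsilon (logged).
    k : int
        Inner dimension (number of clusters); must satisfy k < min(R, C).
    n_iter : int, default 2000
        Fixed number of update sweeps.
    seed
        Seed for the random positive initialization: entries uniform (0, 1]
        scaled by the mean of M.
    loss : {"kl", "frobenius"}
        Objective minimized by the updates.
    """
    M = _check_nonnegative(M)
    rows, cols = M.shape
    if not 1 <= k < min(rows, cols):
        raise ValueError(f"k = {k} must satisfy 1 <= k < min{M.shape}")
    if loss not in ("kl", "frobenius"):
        raise ValueError(f"unknown loss {loss!r}")
    zero_rows = ~M.any(axis=1)
    zero_cols = ~M.any(axis=0)
    if zero_rows.any() or zero_cols.any():
        logger.info(
            "%d zero rows and %d zero columns lifted by epsilon",
            int(zero_rows.sum()), int(zero_cols.sum()),
        )
        M = np.maximum(M, _EPS)

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    scale = M.mean()
    # uniform over (0, 1]: strictly positive start
    Y = (1.0 - rng.random((rows, k))) * scale
    Z = 1.0 - rng.random((k, cols))

    objective = np.empty(n_iter)
    if loss == "kl":
        for it in range(n_iter):
            R = np.maximum(Y @ Z, _EPS)
            Z *= (Y.T @ (M / R)) / np.maximum(Y.sum(axis=0)[:, None], _EPS)
            R = np.maximum(Y @ Z, _EPS)
            Y *= ((M / R) @ Z.T) / np.maximum(Z.sum(axis=1)[None, :], _EPS)
            objective[it] = _kl_divergence(M, Y @ Z)
    else:
        for it in range(n_iter):
            Z *= (Y.T @ M) / np.maximum(Y.T @ Y @ Z, _EPS)
            Y *= (M @ Z.T) / np.maximum(Y @ Z @ Z.T, _EPS)
            diff = M - Y @ Z
            objective[it] = float(0.5 * np.sum(diff * diff))

    return NMFFactorization(Y=Y, Z=Z, objective=objective, loss=loss)


def assign_clusters(fact: NMFFactorization) -> np.ndarray:
    """Assign each gene (row) to the component with the largest coefficient
    in Y; ties go to the lowest component index (logged)."""
    Y = fact.Y
    labels = np.argmax(Y, axis=1)
    n_ties = int(np.sum(np.sum(Y == Y.max(axis=1, keepdims=True), axis=1) > 1))
    if n_ties:
        logger.info("%d rows with tied coefficients assigned to the lowest index", n_ties)
    return labels


def connectivity_matrix(labels: np.ndarray) -> np.ndarray:
    """Binary co-membership matrix: entry (i, j) = 1 iff label_i == label_j."""
    labels = np.asarray(labels)
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus(
    M: np.ndarray,
    k: int,
    n_restarts: int = 50,
    n_iter: int = 2000,
    seed: int | np.random.Generator | None = None,
    loss: str = "kl",
) -> np.ndarray:
    """Average connectivity matrix over seeded random NMF restarts.

    Entries are co-clustering frequencies in [0, 1] with unit diagonal.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if n_restarts == 1:
        logger.warning("consensus over a single restart is not a stability estimate")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    acc = np.zeros((np.asarray(M).shape[0],) * 2)
    for _ in range(n_restarts):
        fact = nmf_factorize(M, k, n_iter=n_iter, seed=rng, loss=loss)
        acc += connectivity_matrix(assign_clusters(fact))
    return acc / n_restarts


def cophenetic_coefficient(C: np.ndarray) -> float:
    """Cophenetic correlation of a consensus matrix.

    Average-linkage hierarchical clustering is run on the distance matrix
    1 - C; the coefficient is the Pearson correlation between the original
    pairwise distances and the dendrogram's cophenetic distances.  Returns
    NaN when the distances have zero variance (all pairs equally similar).
    """
    C = np.asarray(C, dtype=float)
    if C.shape[0] < 3:
        raise ValueError("cophenetic coefficient needs at least 3 items")
    D = 1.0 - C
    cond = squareform(D, checks=False)
    if np.ptp(cond) == 0.0:
        logger.warning("consensus distances have zero variance; rho undefined")
        return float("nan")
    link = linkage(cond, method="average")
    rho, _ = cophenet(link, cond)
    return float(rho)


def select_stable_k(
    rho: dict[int, float] | np.ndarray,
    drop_threshold: float = 0.05,
    k_min: int | None = None,
) -> int:
    """Largest k before the cophenetic curve's first sharp decline.

    ``rho`` maps each k of a contiguous range to its cophenetic coefficient
    (or is a sequence starting at ``k_min``).  k_stable is the largest k
    such that the curve has stayed within ``drop_threshold`` of its value at
    k_min up to k and the step rho(k) - rho(k+1) exceeds ``drop_threshold``
    (the first sharp decline).  A curve with no such drop returns the
    largest k with a warning.  Missing values inside the range are an error.
    """
    if isinstance(rho, dict):
        ks = sorted(rho)
        vals = np.array([rho[k] for k in ks], dtype=float)
    else:
        vals = np.asarray(rho, dtype=float)
        if k_min is None:
            raise ValueError("k_min is required when rho is a plain sequence")
        ks = list(range(k_min, k_min + vals.size))
    if len(ks) < 2:
        raise ValueError("the cophenetic curve needs at least two k values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError(f"k range is not contiguous: {ks}")
    if not np.all(np.isfinite(vals)):
        bad = [k for k, v in zip(ks, vals) if not np.isfinite(v)]
        raise ValueError(f"cophenetic coefficient undefined at k = {bad}")

    floor = vals[0] - drop_threshold
    for i in range(len(ks) - 1):
        if np.any(vals[: i + 1] < floor):
            break
        if vals[i] - vals[i + 1] > drop_threshold:
            return ks[i]
    logger.warning(
        "no cophenetic drop exceeds %g; returning k_max = %d",
        drop_threshold, ks[-1],
    )
    return ks[-1]


class ConsensusNMF(ClusterMixin, BaseEstimator):
    """Consensus NMF gene clustering with cophenetic model selection.

    For each k in [k_min, k_max] the estimator averages co-clustering over
    ``n_restarts`` seeded NMF runs, scores the consensus matrix by its
    cophenetic coefficient, picks the stable k at the curve's first sharp
    drop, and reads the final gene assignment off the stable consensus
    matrix by cutting its average-linkage dendrogram into k_stable clusters.

    Parameters
    ----------
    k_min, k_max : int, default 2 and 20
        Inclusive range of cluster numbers scanned (clipped to the matrix
        size when the data cannot support k_max).
    n_iter : int, default 2000
        Multiplicative-update iterations per NMF run.
    n_restarts : int, default 50
        Random restarts averaged into each consensus matrix.
    drop_threshold : float, default 0.05
        Decline in the cophenetic coefficient treated as "sharp".
    loss : {"kl", "frobenius"}
    random_state : int or None

    Attributes
    ----------
    consensus_matrices_ : dict  k -> consensus matrix
    cophenetic_ : dict  k -> cophenetic coefficient
    k_stable_ : int
    labels_ : ndarray of cluster labels in {0, ..., k_stable_ - 1}
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 20,
        n_iter: int = 2000,
        n_restarts: int = 50,
        drop_threshold: float = 0.05,
        loss: str = "kl",
        random_state: int | None = None,
    ) -> None:
        self.k_min = k_min
        self.k_max = k_max
        self.n_iter = n_iter
        self.n_restarts = n_restarts
        self.drop_threshold = drop_threshold
        self.loss = loss
        self.random_state = random_state

    def fit(self, M: np.ndarray, y=None) -> "ConsensusNMF":
        M = _check_nonnegative(M)
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        k_hi = min(self.k_max, min(M.shape) - 1)
        if k_hi < self.k_min:
            raise ValueError(
                f"matrix of shape {M.shape} cannot support k >= {self.k_min}"
            )
        if k_hi < self.k_max:
            logger.info("k_max clipped from %d to %d for shape %s",
                        self.k_max, k_hi, M.shape)
        rng = np.random.default_rng(self.random_state)
        self.consensus_matrices_ = {}
        self.cophenetic_ = {}
        for k in range(self.k_min, k_hi + 1):
            C = consensus(
                M, k,
                n_restarts=self.n_restarts,
                n_iter=self.n_iter,
                seed=rng,
                loss=self.loss,
            )
            self.consensus_matrices_[k] = C
            self.cophenetic_[k] = cophenetic_coefficient(C)
        self.k_stable_ = select_stable_k(self.cophenetic_, self.drop_threshold)

        C = self.consensus_matrices_[self.k_stable_]
        link = linkage(squareform(1.0 - C, checks=False), method="average")
        self.labels_ = fcluster(link, t=self.k_stable_, criterion="maxclust") - 1
        return self
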