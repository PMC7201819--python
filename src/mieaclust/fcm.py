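"""Fuzzy c-means machinery: distances, memberships, objective, fitness.

The fuzzy c-means (FCM) model partitions n points x_k among c prototypes v_i
by minimising

    J(X; U, V) = sum_k sum_i u_ik^m * D_ik^2,      D_ik^2 = ||x_k - v_i||^2,

subject to u_ik in [0, 1] and each column of U summing to 1, with fuzzifier
m > 1.  Candidate prototype sets here come either from the classic
alternating-optimisation loop (:func:`fcm_refine` / :class:`FuzzyCMeans`) or
from evolutionary-search chromosomes scored via :func:`evaluate_chromosome`.
The objective is additive over samples, so it can be evaluated in independent
row chunks and summed (:func:`partitioned_objective`), the single-machine
equivalent of a map/reduce fitness evaluation.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

from .data import LabeledDataset

__all__ = [
    "squared_distances",
    "membership_update",
    "objective",
    "fitness",
    "decode",
    "encode",
    "evaluate_chromosome",
    "partitioned_objective",
    "fcm_refine",
    "FuzzyCMeans",
]

logger = logging.getLogger(__name__)

# squared distances at or below this are treated as coincident (degenerate
# membership branch) instead of being fed to the power law, which would blow up
_ZERO_D2 = 1e-12


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, LabeledDataset):
        return X.features
    return np.asarray(X, dtype=float)


def squared_distances(X, V) -> np.ndarray:
    """c x n matrix of squared Euclidean distances D2[i, k] = ||x_k - v_i||^2."""
    Xm = _as_matrix(X)
    Vm = np.atleast_2d(np.asarray(V, dtype=float))
    if Xm.shape[1] != Vm.shape[1]:
        raise ValueError(
            f"dimensionality mismatch: data has p={Xm.shape[1]}, "
            f"centers have p={Vm.shape[1]}"
        )
    return cdist(Vm, Xm, metric="sqeuclidean")


def membership_update(D2: np.ndarray, m: float) -> np.ndarray:
    """Optimal memberships U given squared distances, fuzzifier ``m`` > 1.

    Regular columns get u_ik proportional to d_ik^(-2/(m-1)), normalised to
    sum to 1.  Columns where some d_ik is (numerically) zero put all mass on
    the coincident centers, split uniformly when several coincide.
    """
    if m <= 1:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")
    D2 = np.asarray(D2, dtype=float)
    c, n = D2.shape
    U = np.zeros_like(D2)
    zero = D2 <= _ZERO_D2
    degenerate = zero.any(axis=0)

    if (~degenerate).any():
        sub = D2[:, ~degenerate]
        # normalise by the column minimum before the power law so small m-1
        # cannot overflow; ratios are >= 1
        ratio = sub / sub.min(axis=0, keepdims=True)
        W = ratio ** (-1.0 / (m - 1.0))
        U[:, ~degenerate] = W / W.sum(axis=0, keepdims=True)
    if degenerate.any():
        counts = zero[:, degenerate].sum(axis=0)
        U[:, degenerate] = zero[:, degenerate] / counts
    return U


def objective(U: np.ndarray, D2: np.ndarray, m: float) -> float:
    """FCM objective J = sum_k sum_i u_ik^m * D_ik^2."""
    U = np.asarray(U, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    if m <= 1:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")
    if U.shape != D2.shape:
        raise ValueError(f"shape mismatch: U {U.shape} vs D2 {D2.shape}")
    return float(np.sum((U**m) * D2))


def fitness(J: float) -> float:
    """Fitness transform f = 1 / (J + 1), a strictly decreasing map of J onto (0, 1]."""
    if J < 0:
        raise ValueError(f"objective value must be non-negative, got {J}")
    return 1.0 / (J + 1.0)


def decode(genes: np.ndarray, c: int, p: int) -> np.ndarray:
    """Unpack a flat length-(c*p) chromosome into a c x p prototype matrix."""
    genes = np.asarray(genes, dtype=float)
    if genes.size != c * p:
        raise ValueError(f"chromosome length {genes.size} != c*p = {c * p}")
    return genes.reshape(c, p)


def encode(V: np.ndarray) -> np.ndarray:
    """Flatten a c x p prototype matrix into a chromosome, row-major."""
    return np.asarray(V, dtype=float).reshape(-1).copy()


def evaluate_chromosome(genes, X, c: int, m: float):
    """Score a center-encoding chromosome: decode -> D2 -> U -> J -> f.

    Returns ``(U, J, f)``.
    """
    Xm = _as_matrix(X)
    V = decode(genes, c, Xm.shape[1])
    D2 = squared_distances(Xm, V)
    U = membership_update(D2, m)
    J = objective(U, D2, m)
    return U, J, fitness(J)


def partitioned_objective(X, V, m: float, chunk_size: int) -> float:
    """Evaluate J over contiguous row chunks and sum the partial values.

    Membership columns depend only on their own sample, so the chunked sum
    equals the monolithic objective up to floating-point summation order.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    Xm = _as_matrix(X)
    total = 0.0
    for start in range(0, Xm.shape[0], chunk_size):
        chunk = Xm[start : start + chunk_size]
        D2 = squared_distances(chunk, V)
        U = membership_update(D2, m)
        total += objective(U, D2, m)
    return total


def fcm_refine(
    X,
    V_init: np.ndarray,
    m: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-9,
    rng: np.random.Generator | int | None = None,
):
    """Classic FCM alternating optimisation from a given set of centers.

    Alternates the optimal-membership update with the weighted-mean center
    update v_i = sum_k u_ik^m x_k / sum_k u_ik^m until |dJ| < ``tol`` or
    ``max_iter`` sweeps.  An effectively empty cluster is re-seeded from a
    random data point.  Returns ``(V, U, J_history)``; the J trajectory is
    non-increasing.
    """
    if m <= 1:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")
    if max_iter < 1 or tol <= 0:
        raise ValueError("max_iter must be >= 1 and tol > 0")
    Xm = _as_matrix(X)
    rng = np.random.default_rng(rng)
    V = np.atleast_2d(np.asarray(V_init, dtype=float)).copy()
    history: list[float] = []
    U = None
    for _ in range(max_iter):
        D2 = squared_distances(Xm, V)
        U = membership_update(D2, m)
        history.append(objective(U, D2, m))
        if len(history) > 1 and abs(history[-2] - history[-1]) < tol:
            break
        Um = U**m
        mass = Um.sum(axis=1)
        empty = mass <= 0
        if empty.any():
            for i in np.where(empty)[0]:
                V[i] = Xm[rng.integers(Xm.shape[0])]
                logger.warning("re-seeded empty cluster %d from a data point", i)
            mass = np.where(empty, 1.0, mass)
            V[~empty] = (Um[~empty] @ Xm) / mass[~empty, None]
        else:
            V = (Um @ Xm) / mass[:, None]
    return V, U, np.asarray(history)


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering by alternating optimisation.

    The baseline the evolutionary optimiser is compared against: a local
    descent on J from a random (or user-supplied) initialisation.

    Parameters
    ----------
    n_clusters : int
        Number of prototypes c.
    fuzzifier : float
        Membership softness exponent m > 1; 2.0 is the conventional choice.
    init : "random" or array of shape (c, p)
        Initial centers; "random" draws uniformly within each feature's range.
    max_iter, tol : convergence controls on |dJ|.
    random_state : int, Generator or None
        Seeds initialisation and empty-cluster re-seeding.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (c, p)
    membership_ : ndarray of shape (c, n)
    labels_ : ndarray of shape (n,) — argmax defuzzification of membership_
    objective_history_ : ndarray — J per sweep, non-increasing
    objective_ : float — final J
    """

    def __init__(
        self,
        n_clusters: int = 2,
        fuzzifier: float = 2.0,
        init="random",
        max_iter: int = 100,
        tol: float = 1e-9,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.fuzzifier = fuzzifier
        self.init = init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        Xm = _as_matrix(X)
        if Xm.ndim != 2 or Xm.shape[0] < 2:
            raise ValueError("X must be 2-D with at least two samples")
        if not 1 <= self.n_clusters <= Xm.shape[0] - 1:
            raise ValueError("need 1 <= n_clusters <= n_samples - 1")
        rng = np.random.default_rng(self.random_state)
        if isinstance(self.init, str) and self.init == "random":
            lo, hi = Xm.min(axis=0), Xm.max(axis=0)
            V0 = rng.uniform(lo, hi, size=(self.n_clusters, Xm.shape[1]))
        else:
            V0 = np.asarray(self.init, dtype=float)
        V, U, hist = fcm_refine(Xm, V0, self.fuzzifier, self.max_iter, self.tol, rng)
        self.cluster_centers_ = V
        self.membership_ = U
        self.labels_ = U.argmax(axis=0)
        self.objective_history_ = hist
        self.objective_ = float(hist[-1])
        self.n_features_in_ = Xm.shape[1]
        return self

    def predict(self, X):
        Xm = _as_matrix(X)
        U = membership_update(
            squared_distances(Xm, self.cluster_centers_), self.fuzzifier
        )
        return U.argmax(axis=0)
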