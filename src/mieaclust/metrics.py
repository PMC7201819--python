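"""External validation of clusterings against reference class labels.

Given reference classes i and produced clusters j with contingency counts
n_ij, class sizes n_i and cluster sizes n_j:

    recall    r(i, j) = n_ij / n_i
    precision p(i, j) = n_ij / n_j
    F(i, j)   = 2 r p / (r + p)            (0 when r + p = 0)
    F         = sum_i (n_i / n) * max_j F(i, j)    with upper bound 1,

plus majority-mapping accuracy: each cluster is assigned its most frequent
reference class, and accuracy is the fraction of samples mapped correctly,
sum_j max_i n_ij / n.  Adjusted Rand and normalised mutual information are
exposed as auxiliary cross-checks only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

__all__ = [
    "Contingency",
    "contingency",
    "pair_f",
    "f_measure",
    "per_class_f",
    "majority_accuracy",
    "cross_check_indices",
]


@dataclass
class Contingency:
    """K x C count matrix of reference classes (rows) vs clusters (columns)."""

    n_ij: np.ndarray
    class_ids: np.ndarray
    cluster_ids: np.ndarray

    @property
    def n_i(self) -> np.ndarray:
        return self.n_ij.sum(axis=1)

    @property
    def n_j(self) -> np.ndarray:
        return self.n_ij.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.n_ij.sum())


def contingency(labels, clusters) -> Contingency:
    """Cross-tabulate reference labels against cluster assignments."""
    labels = np.asarray(labels)
    clusters = np.asarray(clusters)
    if labels.shape != clusters.shape or labels.ndim != 1:
        raise ValueError("labels and clusters must be equal-length 1-D arrays")
    if labels.size == 0:
        raise ValueError("empty label arrays")
    class_ids, li = np.unique(labels, return_inverse=True)
    cluster_ids, ci = np.unique(clusters, return_inverse=True)
    n_ij = np.zeros((class_ids.size, cluster_ids.size), dtype=int)
    np.add.at(n_ij, (li, ci), 1)
    return Contingency(n_ij, class_ids, cluster_ids)


def pair_f(n_ij: float, n_i: float, n_j: float) -> tuple[float, float, float]:
    """Per-(class, cluster) F with its recall and precision: (F, r, p)."""
    if n_i <= 0 or n_j <= 0:
        raise ValueError("class and cluster sizes must be positive")
    r = n_ij / n_i
    p = n_ij / n_j
    F = 0.0 if r + p == 0 else 2.0 * r * p / (r + p)
    return F, r, p


def per_class_f(cont: Contingency) -> np.ndarray:
    """Best F(i, j) over non-empty clusters, per reference class."""
    n_i, n_j = cont.n_i, cont.n_j
    live = n_j > 0
    best = np.zeros(cont.n_ij.shape[0])
    for i in range(cont.n_ij.shape[0]):
        best[i] = max(
            pair_f(cont.n_ij[i, j], n_i[i], n_j[j])[0]
            for j in range(cont.n_ij.shape[1])
            if live[j]
        )
    return best


def f_measure(cont: Contingency) -> float:
    """Class-size-weighted best pair F; 1 means perfect recovery."""
    return float(np.sum(cont.n_i / cont.n * per_class_f(cont)))


def majority_accuracy(cont: Contingency) -> float:
    """Fraction correct after mapping each cluster to its majority class."""
    return float(cont.n_ij.max(axis=0).sum() / cont.n)


def cross_check_indices(labels, clusters) -> dict[str, float]:
    """Auxiliary agreement indices (ARI, NMI) for sanity checks; not part of
    the F-measure/accuracy reporting."""
    return {
        "ari": float(adjusted_rand_score(labels, clusters)),
        "nmi": float(normalized_mutual_info_score(labels, clusters)),
    }
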