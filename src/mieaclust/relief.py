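"""Relief feature weighting with repeated-run averaging and pruning.

Relief (Kira & Rendell) scores each feature by how well it separates a
randomly sampled instance R from its nearest neighbour of another class
(nearest miss) relative to its nearest neighbour of the same class (nearest
hit):

    w_d += diff(d, R, miss) - diff(d, R, hit),   averaged over the samples,

where diff is the absolute difference on min-max-scaled values, so every
weight lies in [-1, 1].  Because the score depends on which instances are
sampled, the weights are averaged over repeated runs (20 by default) before
low-weight features are pruned by a threshold or bottom-k rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import LabeledDataset, min_max_scale

__all__ = [
    "WeightReport",
    "relief_weights",
    "averaged_weights",
    "select_features",
    "ReliefWeighter",
]


@dataclass
class WeightReport:
    """Averaged Relief weights plus the per-run matrix they came from."""

    weights: np.ndarray
    per_run_weights: np.ndarray
    repeats: int
    removed: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    threshold_rule: str | None = None


def _check_labels(ds: LabeledDataset) -> np.ndarray:
    if ds.labels is None:
        raise ValueError("Relief weighting requires class labels")
    classes, counts = np.unique(ds.labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("Relief weighting requires at least two classes")
    if np.any(counts < 2):
        raise ValueError("every class needs at least two members")
    return ds.labels


def relief_weights(ds: LabeledDataset, n_samples: int, rng) -> np.ndarray:
    """Single Relief pass: length-p weights in [-1, 1].

    Instances are sampled without replacement when ``n_samples <= n`` (with
    replacement otherwise); hit/miss neighbours are found by Euclidean
    distance over all min-max-scaled features, excluding the instance itself.
    """
    labels = _check_labels(ds)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    scaled, _, _ = min_max_scale(ds)
    X = scaled.features
    n, p = X.shape
    rng = np.random.default_rng(rng)
    idx = rng.choice(n, size=n_samples, replace=n_samples > n)

    w = np.zeros(p)
    for i in idx:
        d = np.linalg.norm(X - X[i], axis=1)
        d[i] = np.inf
        same = labels == labels[i]
        hit = np.where(same, d, np.inf).argmin()
        miss = np.where(same, np.inf, d).argmin()
        w += np.abs(X[i] - X[miss]) - np.abs(X[i] - X[hit])
    return w / n_samples


def averaged_weights(
    ds: LabeledDataset,
    n_samples: int,
    repeats: int = 20,
    base_seed: int = 0,
) -> WeightReport:
    """Average ``repeats`` independent Relief passes (seeds base_seed + r)."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    runs = np.vstack(
        [relief_weights(ds, n_samples, base_seed + r) for r in range(repeats)]
    )
    return WeightReport(runs.mean(axis=0), runs, repeats)


def select_features(
    report: WeightReport | np.ndarray,
    rule: str = "threshold",
    threshold: float | None = None,
    k: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition feature indices into (kept, removed).

    ``threshold``: remove features with weight < threshold.  ``bottom_k``:
    remove the k smallest weights, ties broken by removing the lower index
    first.
    """
    weights = report.weights if isinstance(report, WeightReport) else np.asarray(report)
    p = weights.size
    all_idx = np.arange(p)
    if rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule needs a threshold value")
        removed = all_idx[weights < threshold]
    elif rule == "bottom_k":
        if k is None:
            raise ValueError("bottom_k rule needs k")
        if k >= p:
            raise ValueError(f"cannot remove k={k} of p={p} features")
        removed = np.sort(np.argsort(weights, kind="stable")[:k])
    else:
        raise ValueError(f"unknown rule {rule!r}")
    kept = np.setdiff1d(all_idx, removed)
    if isinstance(report, WeightReport):
        report.removed = removed
        report.threshold_rule = rule
    return kept, removed


class ReliefWeighter(TransformerMixin, BaseEstimator):
    """Relief-based feature weighting / pruning transformer.

    Fits averaged Relief weights on labelled data and (optionally) drops
    low-weight features on transform.

    Parameters
    ----------
    n_samples : int or None
        Instances sampled per run; None means all of them.
    repeats : int
        Independent runs averaged (default 20).
    rule : {"none", "threshold", "bottom_k"}
        Pruning rule applied after averaging.
    threshold, k : rule parameters.
    random_state : int
        Base seed; run r uses random_state + r.

    Attributes
    ----------
    weights_ : ndarray of shape (p,)
    per_run_weights_ : ndarray of shape (repeats, p)
    kept_idx_, removed_idx_ : index partitions of [0, p)
    """

    def __init__(
        self,
        n_samples: int | None = None,
        repeats: int = 20,
        rule: str = "none",
        threshold: float | None = None,
        k: int | None = None,
        random_state: int = 0,
    ):
        self.n_samples = n_samples
        self.repeats = repeats
        self.rule = rule
        self.threshold = threshold
        self.k = k
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, LabeledDataset):
            ds = X
        else:
            if y is None:
                raise ValueError("y (class labels) is required")
            ds = LabeledDataset(np.asarray(X, dtype=float), np.asarray(y))
        n_samples = self.n_samples if self.n_samples is not None else ds.n
        report = averaged_weights(
            ds, n_samples, self.repeats, base_seed=int(self.random_state)
        )
        if self.rule == "none":
            kept = np.arange(ds.p)
            removed = np.array([], dtype=int)
        else:
            kept, removed = select_features(
                report, self.rule, threshold=self.threshold, k=self.k
            )
        self.weights_ = report.weights
        self.per_run_weights_ = report.per_run_weights
        self.kept_idx_ = kept
        self.removed_idx_ = removed
        self.n_features_in_ = ds.p
        return self

    def transform(self, X):
        Xm = X.features if isinstance(X, LabeledDataset) else np.asarray(X, dtype=float)
        return Xm[:, self.kept_idx_]
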