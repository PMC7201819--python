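"""Loading, scaling and simulation of labelled numeric tables.

Clinical tabular datasets in the UCI style are delimited text files with an
optional record-ID column, numeric feature columns (``?`` marking a missing
value) and an optional class-label column.  This module reads and writes that
dialect, provides min-max feature scaling, and generates labelled
Gaussian-mixture fixtures so the clustering and feature-weighting code can be
exercised without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "MixtureSpec",
    "load_table",
    "write_table",
    "min_max_scale",
    "inverse_min_max",
    "generate_mixture",
]


@dataclass
class LabeledDataset:
    """An n x p numeric feature matrix with optional integer class labels.

    Parameters
    ----------
    features : ndarray of shape (n, p)
        Numeric feature matrix, any real units.
    labels : ndarray of shape (n,) of int, optional
        Reference class per sample, contiguous codes ``0..K-1``.
    feature_names : list of str, optional
        Column names; defaults to ``f0..f{p-1}``.
    """

    features: np.ndarray
    labels: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, p = self.features.shape
        if n < 1 or p < 1:
            raise ValueError("dataset must have at least one row and one column")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values after loading")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels must have exactly one entry per sample")
            if np.unique(self.labels).size < 1:
                raise ValueError("labels must contain at least one class")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(p)]
        elif len(self.feature_names) != p:
            raise ValueError("feature_names length must equal p")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]


@dataclass
class MixtureSpec:
    """Parameters of a labelled isotropic Gaussian mixture fixture.

    ``spreads`` are per-cluster standard deviations (scalar broadcasts);
    ``weights`` are mixing proportions summing to 1 (uniform if omitted).
    ``noise_features`` appends that many uniform[0, 1] columns carrying no
    class information, for feature-weighting tests.
    """

    means: np.ndarray
    spreads: float | Sequence[float] = 1.0
    weights: Sequence[float] | None = None
    noise_features: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        c = self.means.shape[0]
        self.spreads = np.broadcast_to(
            np.asarray(self.spreads, dtype=float), (c,)
        ).copy()
        if np.any(self.spreads < 0):
            raise ValueError("cluster spreads must be non-negative")
        if self.weights is None:
            self.weights = np.full(c, 1.0 / c)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (c,):
                raise ValueError("need one weight per cluster")
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")
        if self.noise_features < 0:
            raise ValueError("noise_features must be >= 0")

    @property
    def c_true(self) -> int:
        return self.means.shape[0]

    @property
    def p_informative(self) -> int:
        return self.means.shape[1]


def _resolve_column(col, names: list[str] | None, ncols: int) -> int:
    if isinstance(col, str):
        if names is None or col not in names:
            raise ValueError(f"column {col!r} not found in header")
        return names.index(col)
    idx = int(col)
    if idx < 0:
        idx += ncols
    if not 0 <= idx < ncols:
        raise ValueError(f"column index {col} out of range for {ncols} columns")
    return idx


def load_table(
    path,
    label_column=None,
    id_column=None,
    missing_policy: str = "drop_row",
    delimiter: str = ",",
    header: str | bool = "auto",
) -> LabeledDataset:
    """Read a UCI-style delimited table into a :class:`LabeledDataset`.

    ``?`` cells are missing values handled per ``missing_policy``
    (``"drop_row"`` or ``"mean_impute"``).  ``label_column`` / ``id_column``
    may be a header name or a (possibly negative) integer position;
    both are removed from the feature matrix.  ``header="auto"`` sniffs a
    header row by checking whether the first line parses as numbers.
    """
    if missing_policy not in ("drop_row", "mean_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(
        path, sep=delimiter, header=None, dtype=str, skipinitialspace=True
    )
    raw = raw.apply(lambda s: s.str.strip())
    names: list[str] | None = None

    def _is_numeric_cell(v) -> bool:
        if pd.isna(v) or v == "?":
            return True
        try:
            float(v)
            return True
        except ValueError:
            return False

    has_header = bool(header) if header != "auto" else not all(
        _is_numeric_cell(v) for v in raw.iloc[0]
    )
    if has_header:
        names = [str(v) for v in raw.iloc[0]]
        raw = raw.iloc[1:].reset_index(drop=True)
    if raw.empty:
        raise ValueError("table contains no data rows")

    ncols = raw.shape[1]
    drop: list[int] = []
    label_idx = None
    if id_column is not None:
        drop.append(_resolve_column(id_column, names, ncols))
    if label_column is not None:
        label_idx = _resolve_column(label_column, names, ncols)
        drop.append(label_idx)
    feat_cols = [j for j in range(ncols) if j not in drop]
    if not feat_cols:
        raise ValueError("no feature columns remain after removing id/label")

    X = np.empty((raw.shape[0], len(feat_cols)))
    for out_j, j in enumerate(feat_cols):
        colname = names[j] if names else str(j)
        for i, v in enumerate(raw.iloc[:, j]):
            if pd.isna(v) or v == "?":
                X[i, out_j] = np.nan
                continue
            try:
                X[i, out_j] = float(v)
            except ValueError:
                raise ValueError(
                    f"cannot parse value {v!r} at row {i}, column {colname!r}"
                ) from None

    labels = None
    if label_idx is not None:
        lab_raw = raw.iloc[:, label_idx]
        keep_lab = ~(lab_raw.isna() | (lab_raw == "?"))
    else:
        keep_lab = pd.Series(True, index=raw.index)

    row_ok = keep_lab.to_numpy()
    if missing_policy == "drop_row":
        row_ok &= ~np.isnan(X).any(axis=1)
        X = X[row_ok]
    else:
        X = X[row_ok]
        col_mean = np.nanmean(X, axis=0) if X.size else np.array([])
        if X.size and np.any(np.isnan(col_mean)):
            raise ValueError("a feature column is entirely missing; cannot impute")
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
    if X.shape[0] == 0:
        raise ValueError("all rows were dropped by the missing-value policy")

    if label_idx is not None:
        lab_vals = raw.iloc[:, label_idx].to_numpy()[row_ok]
        # first-appearance order -> contiguous codes, stable contingency tables
        seen: dict[str, int] = {}
        labels = np.array([seen.setdefault(v, len(seen)) for v in lab_vals])

    feature_names = [names[j] for j in feat_cols] if names else []
    return LabeledDataset(X, labels, feature_names)


def write_table(
    ds: LabeledDataset,
    path,
    delimiter: str = ",",
    header: bool = True,
    label_name: str = "label",
) -> None:
    """Write a dataset back to the same CSV dialect :func:`load_table` reads."""
    df = pd.DataFrame(ds.features, columns=ds.feature_names)
    if ds.labels is not None:
        df[label_name] = ds.labels
    df.to_csv(path, sep=delimiter, header=header, index=False, float_format="%.17g")


def min_max_scale(ds: LabeledDataset) -> tuple[LabeledDataset, np.ndarray, np.ndarray]:
    """Map every feature onto [0, 1]; constant features map to 0.

    Returns the scaled dataset together with the per-feature ``(min, max)``
    vectors so prototypes can be mapped back with :func:`inverse_min_max`.
    """
    lo = ds.features.min(axis=0)
    hi = ds.features.max(axis=0)
    rng = hi - lo
    safe = np.where(rng > 0, rng, 1.0)
    scaled = (ds.features - lo) / safe
    scaled[:, rng == 0] = 0.0
    out = LabeledDataset(scaled, ds.labels, list(ds.feature_names))
    return out, lo, hi


def inverse_min_max(V: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Map points from [0, 1] scale back to original units."""
    return np.asarray(V) * (np.asarray(hi) - np.asarray(lo)) + np.asarray(lo)


def generate_mixture(spec: MixtureSpec, n: int) -> LabeledDataset:
    """Draw ``n`` labelled samples from the mixture described by ``spec``.

    Per-cluster sample counts follow the weights exactly (largest-remainder
    apportionment) rather than being drawn i.i.d.; in the zero-spread limit
    with ``n == c_true`` and uniform weights the output is therefore one exact
    copy of each mean row.  Row order is shuffled.  Identical seed gives
    byte-identical output.
    """
    c = spec.c_true
    if n < c:
        raise ValueError(f"need n >= c_true ({c}), got n={n}")
    rng = np.random.default_rng(spec.seed)

    exact = np.asarray(spec.weights) * n
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    if remainder:
        order = np.argsort(-(exact - counts), kind="stable")
        counts[order[:remainder]] += 1

    blocks, labels = [], []
    for k in range(c):
        z = rng.standard_normal((counts[k], spec.p_informative))
        blocks.append(spec.means[k] + spec.spreads[k] * z)
        labels.append(np.full(counts[k], k))
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]

    names = [f"f{j}" for j in range(spec.p_informative)]
    if spec.noise_features:
        noise = rng.uniform(0.0, 1.0, size=(n, spec.noise_features))
        X = np.hstack([X, noise])
        names += [f"noise{j}" for j in range(spec.noise_features)]
    return LabeledDataset(X, y, names)
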