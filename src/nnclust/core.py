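"""Clustering objective: pooled within-cluster residual scored by the nuclear norm.

The objective for an assignment ``A`` of ``n`` samples to ``K`` clusters is

    NN(A) = sum of singular values of R,   R[i] = M[i] - mean(cluster A[i])

i.e. the nuclear norm (trace norm) of the residual matrix obtained by
subtracting each sample's cluster mean from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

__all__ = [
    "DataMatrix",
    "Assignment",
    "ClusterMeans",
    "normalize_matrix",
    "cluster_means",
    "pooled_residual",
    "nuclear_norm",
    "singular_spectrum",
    "objective",
]

NORMALIZE_METHODS = ("zscore", "minmax", "none")


@dataclass(frozen=True)
class DataMatrix:
    """An n x p numeric matrix of samples by features, post-normalization."""

    values: npt.NDArray[np.float64]
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"data matrix must be 2-D, got shape {values.shape}")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError(f"data matrix must be non-empty, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("data matrix contains non-finite entries")
        object.__setattr__(self, "values", values)
        if self.feature_names is not None:
            names = tuple(self.feature_names)
            if len(names) != values.shape[1]:
                raise ValueError(
                    f"{len(names)} feature names for {values.shape[1]} features"
                )
            object.__setattr__(self, "feature_names", names)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Assignment:
    """A length-n label vector; labels[i] is the cluster of sample i, in {0..K-1}."""

    labels: npt.NDArray[np.int64]
    K: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if labels.size and (labels.min() < 0 or labels.max() >= self.K):
            raise ValueError(f"labels must lie in [0, {self.K}), got range "
                             f"[{labels.min()}, {labels.max()}]")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.labels.size

    def validate_for(self, M: DataMatrix) -> None:
        if self.n != M.n:
            raise ValueError(f"assignment length {self.n} != sample count {M.n}")


@dataclass(frozen=True)
class ClusterMeans:
    """Per-cluster arithmetic means (K x p) and cluster sizes.

    Empty clusters carry an all-zero placeholder center and count 0; no row
    ever references a placeholder, so it never enters the residual.
    """

    centers: npt.NDArray[np.float64]
    counts: npt.NDArray[np.int64]


def normalize_matrix(
    raw: npt.NDArray[np.float64] | DataMatrix,
    method: str = "zscore",
) -> DataMatrix:
    """Column-wise normalization of a raw feature matrix.

    Parameters
    ----------
    raw
        n x p numeric array (or DataMatrix whose values are taken).
    method
        ``"zscore"``: each column to mean 0, sample (ddof=1) sd 1;
        ``"minmax"``: each column rescaled to [0, 1];
        ``"none"``: pass-through.

    Constant columns cannot be scaled; under zscore/minmax they become
    all-zero and a ``UserWarning`` is emitted.
    """
    if method not in NORMALIZE_METHODS:
        raise ValueError(f"unknown normalization {method!r}; choose from {NORMALIZE_METHODS}")
    names = raw.feature_names if isinstance(raw, DataMatrix) else None
    X = np.array(raw.values if isinstance(raw, DataMatrix) else raw, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        bad = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(f"non-finite value at row {bad[0]}, column {bad[1]}")

    if method == "none":
        return DataMatrix(X, feature_names=names)

    if method == "zscore":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        constant = sd == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant column(s) mapped to zeros under zscore",
                UserWarning,
                stacklevel=2,
            )
        sd_safe = np.where(constant, 1.0, sd)
        Z = (X - mean) / sd_safe
        Z[:, constant] = 0.0
        return DataMatrix(Z, feature_names=names)

    # minmax
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s) mapped to zeros under minmax",
            UserWarning,
            stacklevel=2,
        )
    span_safe = np.where(constant, 1.0, span)
    Z = (X - lo) / span_safe
    Z[:, constant] = 0.0
    return DataMatrix(Z, feature_names=names)


def cluster_means(M: DataMatrix, A: Assignment) -> ClusterMeans:
    """Arithmetic mean of each cluster's rows. Empty clusters get zero centers."""
    A.validate_for(M)
    K, p = A.K, M.p
    counts = np.bincount(A.labels, minlength=K).astype(np.int64)
    sums = np.zeros((K, p))
    np.add.at(sums, A.labels, M.values)
    centers = np.zeros((K, p))
    nonempty = counts > 0
    centers[nonempty] = sums[nonempty] / counts[nonempty, None]
    return ClusterMeans(centers=centers, counts=counts)


def pooled_residual(M: DataMatrix, A: Assignment) -> npt.NDArray[np.float64]:
    """Residual matrix: row i is ``M[i] - center[A[i]]``.

    Rows of any non-empty cluster sum to the zero vector by construction.
    """
    means = cluster_means(M, A)
    return M.values - means.centers[A.labels]


def nuclear_norm(X: npt.NDArray[np.float64]) -> float:
    """Sum of singular values of ``X`` (the trace norm)."""
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("nuclear_norm requires finite entries")
    return float(np.linalg.svd(X, compute_uv=False).sum())


def singular_spectrum(X: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
    """Singular values of ``X``, sorted non-increasing."""
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("singular_spectrum requires finite entries")
    return np.linalg.svd(X, compute_uv=False)


def objective(A: Assignment, M: DataMatrix) -> float:
    """NN(A): nuclear norm of the pooled within-cluster residual of M under A."""
    return nuclear_norm(pooled_residual(M, A))
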