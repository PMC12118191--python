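"""Descriptor pretreatment: truncation, variance filter, scaling, PCA.

The pipeline order is fixed: (1) strictly positive energies are truncated to
zero, (2) columns whose sample standard deviation (n-1 denominator) falls
below a threshold are removed, (3) optional standardization, (4) PCA by
singular value decomposition of the centered (optionally scaled) matrix.
Component signs are fixed so that each component's largest-magnitude loading
is positive, giving a reproducible orientation.

All statistics are frozen at fit time from the training rows only;
``transform`` replays the frozen sequence on new data without updating them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FittedPretreatment",
    "PretreatmentConfig",
    "PretreatmentError",
    "filter_low_variance",
    "fit_pretreatment",
    "transform",
    "truncate_positive",
]


class PretreatmentError(ValueError):
    """Raised for invalid pretreatment configuration or data."""


@dataclass
class PretreatmentConfig:
    truncate_positive: bool = True
    std_threshold: float = 0.0
    standardize: bool = False
    n_components: int = 2

    def __post_init__(self) -> None:
        if self.std_threshold < 0:
            raise PretreatmentError("std_threshold must be >= 0")
        if self.n_components < 1:
            raise PretreatmentError("n_components must be >= 1")


def _values(X) -> np.ndarray:
    """Accept an InteractionEnergyMatrix or a plain 2-D array."""
    arr = X.values if hasattr(X, "values") else X
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise PretreatmentError("expected a 2-D matrix")
    return arr


def _rewrap(X, values: np.ndarray, columns: list[int] | None = None):
    """Return the same container type as X with new values (and columns)."""
    if hasattr(X, "values") and hasattr(X, "columns"):
        from koffkit.energetics import InteractionEnergyMatrix

        cols = X.columns if columns is None else [X.columns[i] for i in columns]
        return InteractionEnergyMatrix(list(X.complex_ids), list(cols), values)
    return values


def truncate_positive(X):
    """Replace every strictly positive entry by zero (idempotent)."""
    arr = _values(X)
    return _rewrap(X, np.minimum(arr, 0.0))


def filter_low_variance(X, std_threshold: float):
    """Drop columns with sample standard deviation below ``std_threshold``.

    Returns ``(X_reduced, retained_columns)`` with column order preserved.
    """
    arr = _values(X)
    if arr.shape[0] < 2:
        raise PretreatmentError("need >= 2 rows to estimate standard deviations")
    stds = np.std(arr, axis=0, ddof=1)
    retained = [int(j) for j in range(arr.shape[1]) if stds[j] >= std_threshold]
    if not retained:
        raise PretreatmentError(
            f"std_threshold={std_threshold} removed every column; lower the threshold"
        )
    return _rewrap(X, arr[:, retained], retained), retained


@dataclass
class FittedPretreatment:
    """Frozen training statistics for the truncate-filter-scale-PCA sequence."""

    n_input_columns: int
    truncate: bool
    standardize: bool
    retained_columns: list[int]
    column_means: np.ndarray
    column_scales: np.ndarray
    pca_mean: np.ndarray
    pca_loadings: np.ndarray  # (n_components, n_retained), rows orthonormal
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.column_means = np.asarray(self.column_means, dtype=float)
        self.column_scales = np.asarray(self.column_scales, dtype=float)
        self.pca_mean = np.asarray(self.pca_mean, dtype=float)
        self.pca_loadings = np.asarray(self.pca_loadings, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        gram = self.pca_loadings @ self.pca_loadings.T
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise PretreatmentError("PCA loadings rows must be orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise PretreatmentError("explained_variance must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.pca_loadings.shape[0]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_input_columns": self.n_input_columns,
            "truncate": self.truncate,
            "standardize": self.standardize,
            "retained_columns": self.retained_columns,
            "column_means": self.column_means.tolist(),
            "column_scales": self.column_scales.tolist(),
            "pca_mean": self.pca_mean.tolist(),
            "pca_loadings": self.pca_loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedPretreatment":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(**payload)


def fit_pretreatment(X, cfg: PretreatmentConfig) -> FittedPretreatment:
    """Fit the four-step pretreatment on training rows only.

    ``cfg.n_components`` must not exceed min(n_rows - 1, retained dimension).
    """
    arr = _values(X)
    n, d = arr.shape
    if cfg.truncate_positive:
        arr = np.minimum(arr, 0.0)
    if n < 2:
        raise PretreatmentError("need >= 2 training rows")
    stds = np.std(arr, axis=0, ddof=1)
    retained = [int(j) for j in range(d) if stds[j] >= cfg.std_threshold]
    if not retained:
        raise PretreatmentError(
            f"std_threshold={cfg.std_threshold} removed every column; lower the threshold"
        )
    arr = arr[:, retained]
    means = arr.mean(axis=0)
    if cfg.standardize:
        scales = np.std(arr, axis=0, ddof=1)
        scales[scales == 0.0] = 1.0
        work = (arr - means) / scales
    else:
        scales = np.ones(len(retained))
        work = arr

    max_comp = min(n - 1, len(retained))
    if cfg.n_components > max_comp:
        raise PretreatmentError(
            f"n_components={cfg.n_components} exceeds min(n_rows - 1, retained) = {max_comp}"
        )
    pca_mean = work.mean(axis=0)
    centered = work - pca_mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = vt[: cfg.n_components]
    # fix orientation: largest-magnitude loading of each component is positive
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    explained = (s[: cfg.n_components] ** 2) / (n - 1)
    return FittedPretreatment(
        n_input_columns=d,
        truncate=cfg.truncate_positive,
        standardize=cfg.standardize,
        retained_columns=retained,
        column_means=means,
        column_scales=scales,
        pca_mean=pca_mean,
        pca_loadings=loadings,
        explained_variance=explained,
    )


def transform(fitted: FittedPretreatment, X) -> np.ndarray:
    """Apply the frozen truncate-filter-scale-project sequence to new rows."""
    arr = _values(X)
    if arr.shape[1] != fitted.n_input_columns:
        raise PretreatmentError(
            f"column count {arr.shape[1]} does not match the fitted "
            f"{fitted.n_input_columns} input columns"
        )
    if fitted.truncate:
        arr = np.minimum(arr, 0.0)
    arr = arr[:, fitted.retained_columns]
    if fitted.standardize:
        arr = (arr - fitted.column_means) / fitted.column_scales
    return (arr - fitted.pca_mean) @ fitted.pca_loadings.T
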