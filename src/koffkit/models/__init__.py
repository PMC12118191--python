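"""Regressor registry: the in-repo BNN plus seven baseline regressors.

Every kind is exposed behind one ``fit(X, y)`` / ``predict(X)`` contract.
The seven baselines are backed by scikit-learn; the gradient-boosting kind
is registered under the name "xgboost" for roster compatibility but uses
``sklearn.ensemble.GradientBoostingRegressor`` as its backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from koffkit.models.bnn import (
    BNNConfig,
    BNNDivergenceError,
    BNNRegressor,
    PosteriorPrediction,
)

__all__ = [
    "BNNConfig",
    "BNNDivergenceError",
    "BNNRegressor",
    "ModelError",
    "PosteriorPrediction",
    "REGRESSOR_KINDS",
    "RegressorSpec",
    "make_regressor",
]

REGRESSOR_KINDS = ("bnn", "plsr", "br", "gpr", "pcr", "rf", "svm", "xgboost")


class ModelError(ValueError):
    """Raised for unknown regressor kinds or bad specs."""


@dataclass
class RegressorSpec:
    kind: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind.lower() not in REGRESSOR_KINDS:
            raise ModelError(
                f"unknown regressor kind {self.kind!r}; expected one of {REGRESSOR_KINDS}"
            )


class _SklearnAdapter:
    """Uniform wrapper: 1-D predictions, numpy in/out."""

    def __init__(self, estimator, n_components: int | None = None):
        self._est = estimator
        self.n_components = n_components

    def fit(self, X, y):
        self._est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float).ravel())
        return self

    def predict(self, X):
        return np.asarray(self._est.predict(np.asarray(X, dtype=float))).ravel()

    def __repr__(self) -> str:  # pragma: no cover
        return f"_SklearnAdapter({self._est!r})"


def make_regressor(spec: RegressorSpec):
    """Instantiate a regressor from a spec; stochastic kinds honor spec.seed."""
    kind = spec.kind.lower()
    hp = dict(spec.hyperparameters)
    if kind == "bnn":
        return BNNRegressor(BNNConfig(seed=spec.seed, **hp))
    if kind == "plsr":
        from sklearn.cross_decomposition import PLSRegression

        n_components = int(hp.pop("n_components", 2))
        return _SklearnAdapter(
            PLSRegression(n_components=n_components, **hp), n_components=n_components
        )
    if kind == "br":
        from sklearn.linear_model import BayesianRidge

        return _SklearnAdapter(BayesianRidge(**hp))
    if kind == "gpr":
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        kernel = hp.pop("kernel", None)
        if kernel is None:
            # radial-basis kernel with an optimized length scale + noise floor
            kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
                1.0, (1e-2, 1e3)
            ) + WhiteKernel(1e-5, (1e-10, 1e1))
        return _SklearnAdapter(
            GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=spec.seed, **hp
            )
        )
    if kind == "pcr":
        from sklearn.decomposition import PCA
        from sklearn.linear_model import LinearRegression
        from sklearn.pipeline import Pipeline

        n_components = int(hp.pop("n_components", 2))
        pipe = Pipeline(
            [
                ("pca", PCA(n_components=n_components, random_state=spec.seed)),
                ("ols", LinearRegression(**hp)),
            ]
        )
        return _SklearnAdapter(pipe, n_components=n_components)
    if kind == "rf":
        from sklearn.ensemble import RandomForestRegressor

        hp.setdefault("n_estimators", 200)
        return _SklearnAdapter(RandomForestRegressor(random_state=spec.seed, **hp))
    if kind == "svm":
        from sklearn.svm import SVR

        hp.setdefault("kernel", "rbf")
        return _SklearnAdapter(SVR(**hp))
    if kind == "xgboost":
        from sklearn.ensemble import GradientBoostingRegressor

        return _SklearnAdapter(GradientBoostingRegressor(random_state=spec.seed, **hp))
    raise ModelError(f"unknown regressor kind {spec.kind!r}")  # pragma: no cover
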