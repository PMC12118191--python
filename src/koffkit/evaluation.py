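"""Ranked 4:1 splitting, leave-one-out cross-validation, and the 12 indicators.

The ranked split sorts samples ascending by pkoff (stable for ties) and
sends every fifth list position (1-based 5, 10, ...) to the test set, so
``|test| = floor(N / period)``.  Leave-one-out CV refits the full
pretreatment + model composition inside every fold; Q^2 centers the total
sum of squares on the full training-set mean, matching the single y-bar of
the determination-coefficient definition.

Note on the correlation indicator: the printed source formula omits the
squares/square roots in the Pearson denominator (as written it is
identically zero); the standard Pearson correlation coefficient is
implemented instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from koffkit.models import RegressorSpec, make_regressor
from koffkit.pretreatment import PretreatmentConfig, fit_pretreatment, transform

__all__ = [
    "EvaluationError",
    "LooResult",
    "RegressionMetrics",
    "SplitResult",
    "compare_models",
    "compute_metrics",
    "loo_cv",
    "ranked_split",
]

METRIC_COLUMNS = [
    "r2_train", "mae_train", "r_train", "rmse_train",
    "q2_cv", "mae_cv", "r_cv", "rmse_cv",
    "r2_test", "mae_test", "r_test", "rmse_test",
]


class EvaluationError(ValueError):
    """Raised for degenerate inputs or failed CV folds."""


@dataclass
class SplitResult:
    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        overlap = np.intersect1d(self.train_indices, self.test_indices)
        if overlap.size:
            raise EvaluationError(f"train/test overlap at indices {overlap.tolist()}")


@dataclass
class RegressionMetrics:
    """Determination coefficient, MAE, RMSE and Pearson r for one context."""

    r2: float
    mae: float
    rmse: float
    r: float
    context: str  # train | cv | test
    m: int


def _as_pkoff(dataset) -> np.ndarray:
    if hasattr(dataset, "pkoff"):
        return np.asarray(dataset.pkoff, dtype=float)
    return np.asarray(dataset, dtype=float)


def ranked_split(dataset, period: int = 5) -> SplitResult:
    """Sort ascending by pkoff and send every ``period``-th sample to test.

    Stable sort keeps input order for ties.  Returned index arrays refer to
    the original dataset ordering and are sorted ascending.
    """
    y = _as_pkoff(dataset)
    n = y.shape[0]
    if period < 2:
        raise EvaluationError("period must be >= 2")
    if n < period:
        raise EvaluationError(f"need at least period={period} samples, got {n}")
    order = np.argsort(y, kind="stable")
    test = order[period - 1 :: period]
    mask = np.ones(n, dtype=bool)
    mask[test] = False
    return SplitResult(train_indices=np.where(mask)[0], test_indices=np.sort(test))


def compute_metrics(y_exp, y_pred, context: str = "test") -> RegressionMetrics:
    """R^2 = 1 - SSres/SStot, MAE, RMSE, and Pearson r.

    Errors on fewer than 2 points, non-finite values, or zero variance
    (which leaves R^2 and r undefined).
    """
    y_exp = np.asarray(y_exp, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_exp.shape != y_pred.shape or y_exp.size < 2:
        raise EvaluationError("y_exp and y_pred must be equal-length vectors of size >= 2")
    if not (np.all(np.isfinite(y_exp)) and np.all(np.isfinite(y_pred))):
        raise EvaluationError("non-finite values in metric inputs")
    ss_tot = float(np.sum((y_exp - y_exp.mean()) ** 2))
    if ss_tot == 0.0:
        raise EvaluationError("zero variance in y_exp: R^2 and r are undefined")
    ss_res = float(np.sum((y_exp - y_pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    mae = float(np.mean(np.abs(y_exp - y_pred)))
    rmse = float(np.sqrt(np.mean((y_exp - y_pred) ** 2)))
    dp = y_pred - y_pred.mean()
    if float(np.sum(dp * dp)) == 0.0:
        raise EvaluationError("zero variance in y_pred: r is undefined")
    de = y_exp - y_exp.mean()
    r = float(np.sum(de * dp) / np.sqrt(np.sum(de * de) * np.sum(dp * dp)))
    return RegressionMetrics(r2=r2, mae=mae, rmse=rmse, r=r, context=context, m=y_exp.size)


@dataclass
class LooResult:
    q2: float
    mae: float
    r: float
    rmse: float
    predictions: np.ndarray


def _fit_predict(model_source, pre_cfg, X_fit, y_fit, X_eval) -> np.ndarray:
    model = model_source() if callable(model_source) else make_regressor(model_source)
    if pre_cfg is not None:
        fitted = fit_pretreatment(X_fit, pre_cfg)
        X_fit = transform(fitted, X_fit)
        X_eval = transform(fitted, X_eval)
    model.fit(np.asarray(X_fit, dtype=float), y_fit)
    return np.asarray(model.predict(np.asarray(X_eval, dtype=float)), dtype=float).ravel()


def loo_cv(
    model_source: RegressorSpec | Callable[[], object],
    pre_cfg: PretreatmentConfig | None,
    X_train,
    y_train,
) -> LooResult:
    """Leave-one-out CV of the pretreatment + model composition.

    Runs exactly n_train folds; fold i fits on every row except i (refitting
    the pretreatment, so no statistic leaks from the held-out row) and
    predicts row i.  Q^2 uses the full training-set mean in its denominator.

    ``model_source`` is a RegressorSpec or a zero-argument factory; a fresh
    model is built per fold, so stochastic kinds are re-seeded identically.
    """
    X = X_train.values if hasattr(X_train, "values") else np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    n = y.shape[0]
    if X.shape[0] != n:
        raise EvaluationError("X_train and y_train disagree on sample count")
    if n < 3:
        raise EvaluationError("need at least 3 training rows for LOO-CV")
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            preds[i] = _fit_predict(model_source, pre_cfg, X[keep], y[keep], X[i : i + 1])[0]
        except Exception as exc:
            raise EvaluationError(f"LOO fold {i} failed: {exc}") from exc
    press = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise EvaluationError("zero variance in y_train: Q^2 undefined")
    q2 = 1.0 - press / ss_tot
    mae = float(np.mean(np.abs(y - preds)))
    rmse = float(np.sqrt(np.mean((y - preds) ** 2)))
    dp = preds - preds.mean()
    de = y - y.mean()
    denom = np.sqrt(np.sum(de * de) * np.sum(dp * dp))
    r = float(np.sum(de * dp) / denom) if denom > 0 else float("nan")
    return LooResult(q2=q2, mae=mae, r=r, rmse=rmse, predictions=preds)


def select_n_components(
    model_source: RegressorSpec | Callable[[], object],
    pre_cfg: PretreatmentConfig,
    X_train,
    y_train,
    candidates: Sequence[int] | None = None,
) -> tuple[int, dict[int, float]]:
    """Pick the pretreatment component count maximizing LOO-CV Q^2.

    Returns the winning count plus the Q^2 per candidate.  Candidates
    default to every feasible count (1 .. min(n-2, columns)).
    """
    from dataclasses import replace

    X = X_train.values if hasattr(X_train, "values") else np.asarray(X_train, dtype=float)
    n, d = X.shape
    if candidates is None:
        candidates = range(1, min(n - 2, d) + 1)
    scores: dict[int, float] = {}
    for k in candidates:
        scores[k] = loo_cv(model_source, replace(pre_cfg, n_components=k), X, y_train).q2
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


def compare_models(
    specs: Sequence[RegressorSpec],
    dataset,
    X,
    pre_cfg: PretreatmentConfig | None = None,
    period: int = 5,
) -> pd.DataFrame:
    """Evaluate several regressors on one shared split and pretreatment setup.

    Returns one row per model with the 12 indicators plus a ranking by
    ``r2_test`` (1 = best).  Every model sees the same ranked split and the
    same pretreatment configuration (refit per training context).
    """
    Xv = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
    if hasattr(dataset, "complex_ids") and hasattr(X, "complex_ids"):
        if list(dataset.complex_ids) != list(X.complex_ids):
            raise EvaluationError("dataset and matrix complex_id order disagree")
    y = _as_pkoff(dataset)
    if Xv.shape[0] != y.shape[0]:
        raise EvaluationError("matrix and dataset disagree on sample count")
    split = ranked_split(y, period=period)
    tr, te = split.train_indices, split.test_indices

    rows = []
    for spec in specs:
        loo = loo_cv(spec, pre_cfg, Xv[tr], y[tr])
        preds_tr = _fit_predict(spec, pre_cfg, Xv[tr], y[tr], Xv[tr])
        preds_te = _fit_predict(spec, pre_cfg, Xv[tr], y[tr], Xv[te])
        m_tr = compute_metrics(y[tr], preds_tr, "train")
        m_te = compute_metrics(y[te], preds_te, "test")
        name = spec.kind if hasattr(spec, "kind") else getattr(spec, "__name__", "custom")
        rows.append(
            {
                "model": name,
                "r2_train": m_tr.r2, "mae_train": m_tr.mae,
                "r_train": m_tr.r, "rmse_train": m_tr.rmse,
                "q2_cv": loo.q2, "mae_cv": loo.mae, "r_cv": loo.r, "rmse_cv": loo.rmse,
                "r2_test": m_te.r2, "mae_test": m_te.mae,
                "r_test": m_te.r, "rmse_test": m_te.rmse,
            }
        )
    table = pd.DataFrame(rows)
    table["rank_r2_test"] = (
        table["r2_test"].rank(ascending=False, method="min").astype(int)
    )
    return table
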