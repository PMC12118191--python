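import numpy as np
import pytest

from koffkit.complex_io import KineticDataset, KineticEntry
from koffkit.evaluation import (
    EvaluationError,
    compare_models,
    compute_metrics,
    loo_cv,
    ranked_split,
    select_n_components,
)
from koffkit.models import RegressorSpec
from koffkit.pretreatment import PretreatmentConfig, fit_pretreatment, transform


class _MeanOnly:
    """Predicts the training mean everywhere (null model for hand LOO checks)."""

    def fit(self, X, y):
        self._mean = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self._mean)


def _dataset(pkoffs):
    return KineticDataset([KineticEntry(f"c{i}", p) for i, p in enumerate(pkoffs)])


class TestRankedSplit:
    def test_counts_66(self):
        rng = np.random.default_rng(0)
        split = ranked_split(_dataset(rng.permutation(66).astype(float)))
        assert (len(split.train_indices), len(split.test_indices)) == (53, 13)

    def test_counts_35(self):
        rng = np.random.default_rng(1)
        split = ranked_split(_dataset(rng.permutation(35).astype(float)))
        assert (len(split.train_indices), len(split.test_indices)) == (28, 7)

    def test_single_period(self):
        y = [0.3, 2.0, 1.1, 0.9, 1.5]
        split = ranked_split(_dataset(y))
        assert len(split.train_indices) == 4
        # the sorted 5th (largest) sample goes to test
        assert split.test_indices.tolist() == [1]

    def test_every_fifth_ranked_position(self):
        y = np.array([10.0, 1.0, 7.0, 3.0, 9.0, 2.0, 8.0, 4.0, 6.0, 5.0])
        split = ranked_split(_dataset(y))
        # ranked positions 5 and 10 -> values 5.0 and 10.0
        assert sorted(y[split.test_indices].tolist()) == [5.0, 10.0]

    def test_partition_property_exhaustive(self):
        rng = np.random.default_rng(2)
        for n in range(5, 201):
            y = rng.normal(size=n)
            split = ranked_split(y)
            merged = np.concatenate([split.train_indices, split.test_indices])
            assert np.array_equal(np.sort(merged), np.arange(n))
            assert len(split.test_indices) == n // 5

    def test_ties_stable(self):
        y = np.zeros(10)  # fully tied: stable order = input order
        split = ranked_split(y)
        assert split.test_indices.tolist() == [4, 9]

    def test_too_small(self):
        with pytest.raises(EvaluationError):
            ranked_split(_dataset([1.0, 2.0]))


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1, 2, 3], [1, 2, 3])
        assert (m.r2, m.mae, m.rmse, m.r) == (1.0, 0.0, 0.0, 1.0)
        assert m.m == 3

    def test_mean_prediction_r2_zero(self):
        m = compute_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0 + 1e-15])
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        m = compute_metrics([0, 1, 2, 3], [0.5, 1, 2, 2.5])
        assert m.mae == pytest.approx(0.25, abs=1e-4)
        assert m.rmse == pytest.approx(0.35355, abs=1e-4)
        assert m.r2 == pytest.approx(0.9, abs=1e-4)
        assert m.r == pytest.approx(0.98995, abs=1e-4)

    def test_zero_variance_errors(self):
        with pytest.raises(EvaluationError, match="y_exp"):
            compute_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(EvaluationError, match="y_pred"):
            compute_metrics([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])

    def test_mae_le_rmse_property(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            y = rng.normal(size=8)
            p = y + rng.normal(size=8)
            m = compute_metrics(y, p)
            assert m.mae <= m.rmse + 1e-12

    def test_r2_equals_r_squared_for_ols_fit(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        beta = np.polyfit(x, y, 1)
        m = compute_metrics(y, np.polyval(beta, x))
        assert m.r2 == pytest.approx(m.r**2, abs=1e-10)


class TestLooCV:
    def test_hand_example_mean_only(self):
        X = np.zeros((3, 1))
        y = np.array([1.0, 2.0, 3.0])
        res = loo_cv(lambda: _MeanOnly(), None, X, y)
        assert np.allclose(res.predictions, [2.5, 2.0, 1.5])
        assert res.q2 == pytest.approx(-1.25, abs=1e-4)  # 1 - 4.5/2

    def test_fold_count(self):
        calls = []

        class Counting(_MeanOnly):
            def fit(self, X, y):
                calls.append(len(y))
                return super().fit(X, y)

        y = np.arange(7, dtype=float)
        loo_cv(lambda: Counting(), None, np.zeros((7, 1)), y)
        assert len(calls) == 7
        assert all(c == 6 for c in calls)

    def test_deterministic(self, small_matrix):
        rng = np.random.default_rng(5)
        y = rng.normal(size=small_matrix.shape[0])
        spec = RegressorSpec(kind="rf", hyperparameters={"n_estimators": 20}, seed=3)
        cfg = PretreatmentConfig(n_components=2)
        r1 = loo_cv(spec, cfg, small_matrix, y)
        r2 = loo_cv(spec, cfg, small_matrix, y)
        assert np.array_equal(r1.predictions, r2.predictions)

    def test_matches_naive_double_loop(self, small_matrix):
        # independent oracle: explicit per-fold refit of pretreatment + PLSR
        rng = np.random.default_rng(6)
        X = small_matrix.values[:10]
        y = X @ rng.normal(size=X.shape[1]) + rng.normal(0, 0.1, 10)
        cfg = PretreatmentConfig(n_components=3)
        spec = RegressorSpec(kind="plsr", hyperparameters={"n_components": 3})

        naive = np.empty(10)
        from sklearn.cross_decomposition import PLSRegression

        for i in range(10):
            keep = [j for j in range(10) if j != i]
            fitted = fit_pretreatment(X[keep], cfg)
            scores = transform(fitted, X[keep])
            model = PLSRegression(n_components=3).fit(scores, y[keep])
            naive[i] = np.ravel(model.predict(transform(fitted, X[i : i + 1])))[0]
        naive_q2 = 1 - np.sum((y - naive) ** 2) / np.sum((y - y.mean()) ** 2)

        res = loo_cv(spec, cfg, X, y)
        assert np.allclose(res.predictions, naive, atol=1e-8)
        assert res.q2 == pytest.approx(naive_q2, abs=1e-10)

    def test_failing_fold_identified(self):
        class Broken(_MeanOnly):
            def fit(self, X, y):
                raise RuntimeError("boom")

        with pytest.raises(EvaluationError, match="fold 0"):
            loo_cv(lambda: Broken(), None, np.zeros((4, 1)), np.arange(4.0))


class TestCompareModels:
    def _setup(self, n=30, seed=7):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        y = X @ np.array([1.0, -1.0, 0.5, 0.0]) + rng.normal(0, 0.2, n)
        return X, _dataset(y)

    def test_identical_specs_identical_rows(self):
        X, ds = self._setup()
        specs = [RegressorSpec(kind="plsr"), RegressorSpec(kind="plsr")]
        table = compare_models(specs, ds, X, pre_cfg=PretreatmentConfig(n_components=2))
        a, b = table.iloc[0], table.iloc[1]
        for col in table.columns:
            assert a[col] == b[col]

    def test_oracle_predictor_dominates(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 3))
        ds = _dataset(X[:, 0])  # label IS the first descriptor column

        class FirstColumn:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.asarray(X)[:, 0]

        def oracle():
            return FirstColumn()

        table = compare_models([oracle, RegressorSpec(kind="svm")], ds, X, pre_cfg=None)
        oracle_row = table[table["model"] == "oracle"].iloc[0]
        assert oracle_row["r2_test"] == pytest.approx(1.0, abs=1e-12)
        assert oracle_row["rank_r2_test"] == 1

    def test_linear_family_agreement(self):
        X, ds = self._setup(n=60, seed=9)
        table = compare_models(
            [RegressorSpec(kind="plsr", hyperparameters={"n_components": 3}),
             RegressorSpec(kind="br")],
            ds, X, pre_cfg=PretreatmentConfig(n_components=3, truncate_positive=False),
        )
        r2 = table.set_index("model")["r2_test"]
        assert abs(r2["plsr"] - r2["br"]) < 0.05

    def test_reports_all_12_indicators(self):
        X, ds = self._setup()
        table = compare_models([RegressorSpec(kind="br")], ds, X,
                               pre_cfg=PretreatmentConfig(n_components=2))
        expected = {
            "r2_train", "mae_train", "r_train", "rmse_train",
            "q2_cv", "mae_cv", "r_cv", "rmse_cv",
            "r2_test", "mae_test", "r_test", "rmse_test",
        }
        assert expected <= set(table.columns)


def test_select_n_components_prefers_signal_dimension():
    rng = np.random.default_rng(10)
    # rank-2 signal embedded in 6 noisy columns
    basis = rng.normal(size=(2, 6))
    latent = rng.normal(size=(40, 2))
    X = latent @ basis + 0.01 * rng.normal(size=(40, 6))
    y = latent @ np.array([1.0, -2.0]) + 0.05 * rng.normal(size=40)
    best, scores = select_n_components(
        RegressorSpec(kind="br"),
        PretreatmentConfig(n_components=1, truncate_positive=False),
        X, y, candidates=[1, 2, 3, 4],
    )
    assert best == 2
    assert scores[2] > 0.9
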