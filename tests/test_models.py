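"""Regression model families, cross-validation and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromatone.models import (
    PRINTED_EQUATIONS,
    ModelSpec,
    hyperparam_search,
    kfold_cv,
    make_estimator,
    metrics,
    mlr_fit,
    printed_model_predict,
)
from chromatone.ratings import ATTRIBUTES


class TestMLRFit:
    def test_noiseless_univariate_recovery(self):
        x = np.linspace(0, 10, 20)
        beta = mlr_fit(x, 2 + 3 * x)
        assert beta == pytest.approx([2.0, 3.0], abs=1e-10)

    def test_planted_eight_coefficient_model(self, rng):
        X = rng.uniform(1, 5, size=(52, 8))
        true = rng.normal(0, 5, size=8)
        y = X @ true + 12.0
        beta = mlr_fit(X, y)
        assert np.abs(beta - np.r_[12.0, true]).max() < 1e-8

    def test_recovers_planted_signs(self, rng):
        X = rng.uniform(1, 5, size=(52, 8))
        true = np.array([-2.0, -1.5, -3.0, -2.5, -1.0, 2.0, -1.2, -0.8])
        y = X @ true + 30.0
        beta = mlr_fit(X, y)
        assert np.all(np.sign(beta[1:]) == np.sign(true))

    def test_matches_normal_equations(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        beta = mlr_fit(X, y)
        D = np.column_stack([np.ones(30), X])
        expected = np.linalg.solve(D.T @ D, D.T @ y)
        assert beta == pytest.approx(expected, abs=1e-10)

    def test_collinear_columns_named(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 2] = 2 * X[:, 0]
        with pytest.raises(ValueError, match="collinear"):
            mlr_fit(X, rng.normal(size=20), feature_names=["a", "b", "c"])

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValueError, match="n > p"):
            mlr_fit(rng.normal(size=(5, 8)), rng.normal(size=5))


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r, r_norm, mae, rmse = metrics(y, y)
        assert (r, r_norm, mae, rmse) == (pytest.approx(1.0), pytest.approx(1.0), 0.0, 0.0)

    def test_unit_residuals(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        pred = np.array([1.0, -1.0, 2.0, 0.0])
        _, _, mae, rmse = metrics(y, pred)
        assert mae == pytest.approx(1.0)
        assert rmse == pytest.approx(1.0)

    def test_mixed_residuals(self):
        y = np.array([0.0, 1.0, 2.0])
        pred = np.array([0.0, 1.0, 5.0])  # residuals (0, 0, 3)
        _, _, mae, rmse = metrics(y, pred)
        assert mae == pytest.approx(1.0)
        assert rmse == pytest.approx(np.sqrt(3.0))

    def test_constant_prediction_reports_undefined_r(self):
        y = np.array([1.0, 2.0, 3.0])
        r, r_norm, mae, rmse = metrics(y, np.full(3, 2.0))
        assert r is None and r_norm is None
        assert mae == pytest.approx(2.0 / 3.0)

    def test_r_norm_rescaling(self, rng):
        y = rng.normal(size=10)
        pred = -y  # r = -1
        r, r_norm, _, _ = metrics(y, pred)
        assert r == pytest.approx(-1.0)
        assert r_norm == pytest.approx(0.0)

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=50, deadline=None)
    def test_rmse_dominates_mae(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=12)
        pred = y + rng.normal(0, rng.uniform(0.1, 3), size=12)
        _, _, mae, rmse = metrics(y, pred)
        assert rmse >= mae - 1e-12


class TestKFoldCV:
    def test_noiseless_linear_perfect_scores(self, rng):
        X = rng.uniform(0, 1, size=(40, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 4.0
        report = kfold_cv(ModelSpec("MLR", "audio", seed=0), X, y)
        assert report.r == pytest.approx(1.0, abs=1e-9)
        assert report.MAE == pytest.approx(0.0, abs=1e-9)
        assert report.RMSE == pytest.approx(0.0, abs=1e-9)
        assert report.coefficients["intercept"] == pytest.approx(4.0, abs=1e-9)

    def test_same_seed_reproducible(self, rng):
        X = rng.uniform(size=(30, 2))
        y = rng.normal(size=30)
        a = kfold_cv(ModelSpec("RF", "audio", seed=5), X, y)
        b = kfold_cv(ModelSpec("RF", "audio", seed=5), X, y)
        assert a.r == b.r and a.MAE == b.MAE and a.RMSE == b.RMSE

    def test_different_seed_differs_within_cv_noise(self, rng):
        X = rng.uniform(size=(30, 2))
        y = X[:, 0] + 0.3 * rng.normal(size=30)
        a = kfold_cv(ModelSpec("MLR", "audio", seed=1), X, y)
        b = kfold_cv(ModelSpec("MLR", "audio", seed=2), X, y)
        assert a.RMSE != b.RMSE
        assert abs(a.RMSE - b.RMSE) < 0.5 * y.std()

    def test_too_few_samples_suggests_loo(self):
        with pytest.raises(ValueError, match="leave-one-out"):
            kfold_cv(ModelSpec("MLR", "audio", seed=0), np.ones((5, 1)), np.ones(5))


class TestNonlinearFamilies:
    @pytest.mark.parametrize("family", ["SVR", "RF", "BP"])
    def test_fits_constant_target(self, family, rng):
        X = rng.uniform(size=(20, 2))
        y = np.full(20, 3.0)
        est = make_estimator(ModelSpec(family, "audio", seed=0))
        est.fit(X, y)
        assert np.abs(est.predict(X) - 3.0).max() < 0.11  # within SVR epsilon

    def test_rf_more_trees_lower_error(self, rng):
        gains = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.uniform(-2, 2, size=(60, 2))
            y = np.sin(X[:, 0]) * X[:, 1] + 0.1 * r.normal(size=60)
            rmses = {}
            for n_trees in (5, 100):
                spec = ModelSpec("RF", "audio", seed=seed,
                                 hyperparameters={"n_estimators": n_trees})
                rmses[n_trees] = kfold_cv(spec, X, y).RMSE
            gains.append(rmses[5] - rmses[100])
        assert np.mean(gains) > 0  # monotone on average over seeds

    def test_bp_beats_constant_baseline_on_quadratic(self, rng):
        X = rng.uniform(-1, 1, size=(52, 1))
        y = 3.0 * X[:, 0] ** 2
        est = make_estimator(ModelSpec("BP", "audio", seed=1))
        est.fit(X, y)
        train_rmse = float(np.sqrt(np.mean((est.predict(X) - y) ** 2)))
        assert train_rmse < y.std()

    def test_invalid_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="hyperparameters"):
            ModelSpec("SVR", "audio", hyperparameters={"trees": 10})

    def test_visual_direction_needs_target(self):
        with pytest.raises(ValueError, match="target_attribute"):
            ModelSpec("MLR", "visual")


class TestHyperparamSearch:
    def test_budget_one_returns_single_sample(self, rng):
        X = rng.uniform(size=(20, 2))
        y = X[:, 0] + 0.1 * rng.normal(size=20)
        spec = ModelSpec("RF", "audio", seed=3)
        best = hyperparam_search(spec, X, y, budget=1)
        assert set(best) == {"n_estimators"}
        assert 10 <= best["n_estimators"] <= 300

    def test_deterministic_under_seed(self, rng):
        X = rng.uniform(size=(20, 2))
        y = X[:, 0] + 0.1 * rng.normal(size=20)
        spec = ModelSpec("SVR", "audio", seed=4)
        assert hyperparam_search(spec, X, y, budget=3) == hyperparam_search(
            spec, X, y, budget=3
        )

    def test_mlr_has_no_hyperparameters(self, rng):
        X = rng.uniform(size=(20, 2))
        assert hyperparam_search(
            ModelSpec("MLR", "audio", seed=0), X, X[:, 0], budget=5
        ) == {}

    def test_two_stage_near_exhaustive_on_gamma_landscape(self, monkeypatch, rng):
        """With the search restricted to the RBF width gamma, the
        random-then-grid strategy should score close to a fine exhaustive
        grid on a planted nonlinear problem."""
        import chromatone.models as m

        X = rng.uniform(-2, 2, size=(40, 1))
        y = np.sin(2 * X[:, 0]) + 0.05 * rng.normal(size=40)
        space = {"gamma": (1e-3, 10.0, True, False)}
        monkeypatch.setitem(m._SEARCH_SPACES, "SVR", space)

        def score(gamma):
            spec = ModelSpec("SVR", "audio", seed=0,
                             hyperparameters={"gamma": float(gamma)})
            return kfold_cv(spec, X, y).r

        spec = ModelSpec("SVR", "audio", seed=0)
        best = hyperparam_search(spec, X, y, budget=8)
        grid = np.logspace(-3, 1, 25)
        exhaustive_best = max(score(g) for g in grid)
        assert score(best["gamma"]) >= exhaustive_best - 0.05

    def test_zero_budget_rejected(self, rng):
        with pytest.raises(ValueError, match="budget"):
            hyperparam_search(ModelSpec("RF", "audio"), np.ones((12, 1)),
                              np.ones(12), budget=0)


class TestPrintedEquations:
    @pytest.mark.parametrize(
        "eq, x, expected",
        [(17, 0.0, 3.175), (18, 0.0, 3.506), (19, 0.0, 3.364),
         (17, 60.0, 2.695), (23, 0.0, 3.272)],
    )
    def test_visual_equations(self, eq, x, expected):
        assert printed_model_predict(eq, x) == pytest.approx(expected, abs=1e-9)

    def test_audio_equation_at_scale_midpoint(self):
        inputs = {a: 3.0 for a in ATTRIBUTES}
        coef_sum = sum(PRINTED_EQUATIONS[15]["coefficients"].values())
        expected = PRINTED_EQUATIONS[15]["intercept"] + 3.0 * coef_sum
        assert printed_model_predict(15, inputs) == pytest.approx(expected)

    def test_audio_equation_missing_input(self):
        with pytest.raises(ValueError, match="needs input"):
            printed_model_predict(16, {"CW": 3.0})

    def test_unknown_equation(self):
        with pytest.raises(ValueError, match="unknown equation"):
            printed_model_predict(99, 0.0)

    def test_nine_equations_bundled(self):
        assert sorted(PRINTED_EQUATIONS) == list(range(15, 24))
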