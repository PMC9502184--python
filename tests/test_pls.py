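"""PLS fitting, the variance curve, knee-point selection and MCCV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spoilsense import (
    KneePLSRegressor,
    TrainedModel,
    TrainingConfig,
    fit_pls,
    generate_ftir_dataset,
    knee_point,
    mc_cross_validate,
    predict,
    train_pipeline,
    variance_curve,
)


class TestFitPLS:
    def test_noiseless_single_feature(self, rng):
        x1 = rng.normal(size=(15, 1))
        y = 3.0 * x1[:, 0]
        m = fit_pls(x1, y, 1)
        assert np.sqrt(np.mean((m.predict(x1) - y) ** 2)) < 1e-9
        assert m.coefficients[0] == pytest.approx(3.0, rel=1e-9)

    def test_full_rank_equals_least_squares(self, rng):
        # single-response PLS with maximal components is OLS
        for _ in range(50):
            n, p = 20, 5
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            m = fit_pls(X, y, p)
            A = np.column_stack([np.ones(n), X])
            beta = np.linalg.lstsq(A, y, rcond=None)[0]
            np.testing.assert_allclose(m.predict(X), A @ beta, atol=1e-6)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_pls(rng.normal(size=(10, 3)), np.full(10, 2.0), 1)

    def test_component_bounds_enforced(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        with pytest.raises(ValueError, match="n_components"):
            fit_pls(X, y, 0)
        with pytest.raises(ValueError, match="n_components"):
            fit_pls(X, y, 4)


class TestVarianceCurve:
    def test_noiseless_rank_one_saturates_immediately(self, rng):
        x = rng.normal(size=(30, 1))
        X = np.column_stack([x, 2 * x, -x])  # rank 1
        y = 5.0 * x[:, 0]
        curve = variance_curve(X, y, 3)
        np.testing.assert_allclose(curve, 1.0, atol=1e-9)

    def test_orthogonal_response_explains_nothing(self, rng):
        n = 40
        X = rng.normal(size=(n, 3))
        raw = rng.normal(size=n)
        A = np.column_stack([np.ones(n), X])
        y = raw - A @ np.linalg.lstsq(A, raw, rcond=None)[0]  # exactly orthogonal
        curve = variance_curve(X, y, 2)
        assert np.all(curve < 1e-6)

    def test_matches_refit_r_squared(self, rng):
        X = rng.normal(size=(50, 10))
        y = X[:, 0] - 2 * X[:, 4] + 0.3 * rng.normal(size=50)
        curve = variance_curve(X, y, 8)
        for k in range(1, 9):
            m = fit_pls(X, y, k)
            r2 = 1 - np.sum((y - m.predict(X)) ** 2) / np.sum((y - y.mean()) ** 2)
            assert curve[k - 1] == pytest.approx(r2, abs=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_always_non_decreasing(self, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(25, 6))
        y = r.normal(size=25)
        curve = variance_curve(X, y, 5)
        assert np.all(np.diff(curve) >= -1e-10)
        assert np.all((0 <= curve) & (curve <= 1))


class TestKneePoint:
    def test_exact_elbow(self):
        assert knee_point([1, 2, 3, 4, 4, 4, 4]) == 4

    def test_strictly_linear_has_no_knee(self):
        assert knee_point([1, 2, 3, 4, 5, 6, 7]) == 7

    def test_constant_curve_has_no_knee(self):
        assert knee_point([2, 2, 2, 2, 2]) == 5

    def test_saturating_curve_matches_breakpoint_oracle(self):
        ks = np.arange(1, 11, dtype=float)
        vs = 1.0 - 0.5**ks

        def oracle(ks, vs):
            best = None
            for b in range(1, len(ks) - 1):
                a1, c1 = np.polyfit(ks[: b + 1], vs[: b + 1], 1)
                a2, c2 = np.polyfit(ks[b:], vs[b:], 1)
                sse = np.sum((vs[: b + 1] - (a1 * ks[: b + 1] + c1)) ** 2) + np.sum(
                    (vs[b:] - (a2 * ks[b:] + c2)) ** 2
                )
                if best is None or sse < best[0]:
                    x = ks[b] if a1 == a2 else (c2 - c1) / (a1 - a2)
                    best = (sse, x)
            return int(np.clip(np.floor(best[1] + 0.5), ks[0], ks[-1]))

        assert knee_point(vs) == oracle(ks, vs)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            knee_point([1, 2, 3])


class TestMCCV:
    def test_noiseless_linear_gives_tiny_cv_error(self, rng):
        x = rng.normal(size=(24, 1))
        y = 2.0 * x[:, 0]
        cv = mc_cross_validate(x, y, folds=4, repartitions=2, max_components=1, seed=0)
        assert cv.rmse_grid.max() < 1e-6

    def test_grid_shape_contract(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + 0.1 * rng.normal(size=40)
        cv = mc_cross_validate(X, y, folds=5, repartitions=3, max_components=4, seed=1)
        assert cv.rmse_grid.shape == (3, 5, 4)
        assert cv.variance_curve.shape == (4,)

    def test_matches_hand_rolled_loop_oracle(self, rng):
        # n=12, 3 folds, 2 repartitions, reproduced with fit_pls directly
        X = rng.normal(size=(12, 4))
        y = X @ np.array([1.0, -1.0, 0.5, 0.0]) + 0.2 * rng.normal(size=12)
        seed, folds, reps, K = 7, 3, 2, 3
        cv = mc_cross_validate(X, y, folds=folds, repartitions=reps,
                               max_components=K, seed=seed)
        gen = np.random.default_rng(seed)
        expected = np.empty((reps, folds, K))
        for r in range(reps):
            perm = gen.permutation(12)
            for f, test_idx in enumerate(np.array_split(perm, folds)):
                train_idx = np.setdiff1d(perm, test_idx)
                for k in range(1, K + 1):
                    m = fit_pls(X[train_idx], y[train_idx], k)
                    err = m.predict(X[test_idx]) - y[test_idx]
                    expected[r, f, k - 1] = np.sqrt(np.mean(err**2))
        np.testing.assert_allclose(cv.rmse_grid, expected, atol=1e-9)

    def test_tiny_folds_rejected(self, rng):
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        with pytest.raises(ValueError, match="folds"):
            mc_cross_validate(X, y, folds=7, repartitions=1, max_components=1)


class TestKneePLSRegressor:
    def test_sklearn_contract(self):
        from sklearn.utils.estimator_checks import check_estimator

        failures = check_estimator(
            KneePLSRegressor(folds=3, repartitions=1, max_components=2),
            on_fail=None,
        )
        hard = [f for f in failures if f["status"] == "failed"]
        assert not hard, [f["check_name"] for f in hard]

    def test_fixed_component_count(self, rng):
        X = rng.normal(size=(30, 5))
        y = X[:, 0] + 0.1 * rng.normal(size=30)
        est = KneePLSRegressor(n_components=2).fit(X, y)
        assert est.n_components_ == 2
        assert est.predict(X).shape == (30,)


@pytest.fixture(scope="module")
def ftir_model(small_config, small_records):
    ds = generate_ftir_dataset(small_config, small_records)
    config = TrainingConfig(sensor="ftir", folds=5, repartitions=2,
                            cycles=40, seed=0)
    return ds, config, train_pipeline(ds, config)


class TestEndToEndPipeline:
    def test_training_is_deterministic(self, ftir_model):
        ds, config, model = ftir_model
        again = train_pipeline(ds, config)
        assert model.to_json() == again.to_json()

    def test_predict_on_training_reproduces_fitted_values(self, ftir_model):
        ds, _, model = ftir_model
        from spoilsense.pls import _preprocess

        X, fids = _preprocess(ds, model.config)
        cols = [fids.index(f) for f in model.pls.feature_ids]
        fitted = model.pls.predict(X[:, cols])
        np.testing.assert_allclose(predict(model, ds), fitted, atol=1e-9)

    def test_prediction_invariant_to_grid_order(self, ftir_model):
        # ascending vs acquisition (descending) storage: lookup is by value
        ds, _, model = ftir_model
        from spoilsense import SpectralDataset

        ascending = np.argsort(ds.wavenumbers)
        flipped = SpectralDataset(
            ds.wavenumbers[ascending], ds.absorbance[:, ascending], list(ds.records)
        )
        np.testing.assert_allclose(predict(model, flipped), predict(model, ds), atol=1e-9)

    def test_missing_selected_wavenumber_errors_by_name(self, ftir_model):
        ds, _, model = ftir_model
        from spoilsense import SpectralDataset

        victim = model.pls.feature_ids[0]
        keep = ds.wavenumbers != victim
        pruned = SpectralDataset(ds.wavenumbers[keep], ds.absorbance[:, keep],
                                 list(ds.records))
        with pytest.raises(ValueError, match=str(victim)):
            predict(model, pruned)

    def test_cv_rmse_selection_curve_option(self, small_config, small_records):
        from spoilsense import generate_enose_dataset

        ds = generate_enose_dataset(small_config, small_records)
        config = TrainingConfig(sensor="enose", folds=5, repartitions=2,
                                max_components=6, selection_curve="cv_rmse", seed=0)
        model = train_pipeline(ds, config)
        assert 1 <= model.pls.n_components <= 6
        with pytest.raises(ValueError, match="selection_curve"):
            TrainingConfig(selection_curve="aic")

    def test_json_round_trip_preserves_predictions(self, ftir_model, tmp_path):
        ds, _, model = ftir_model
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = TrainedModel.from_json(path)
        np.testing.assert_allclose(predict(loaded, ds), predict(model, ds), atol=1e-12)
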