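"""NIPALS PLS regression, its oracles, and the repeated-split model search."""

import numpy as np
import pandas as pd
import pytest

from hsion import (
    BandMismatchError,
    PLSModel,
    SpectraMatrix,
    fit_plsr,
    load_model,
    predict_timeseries,
    r_squared,
    repeated_split_search,
    rmsep,
    save_model,
)
from conftest import make_annotations


def ols_fitted(X, y):
    Xc = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    return Xc @ beta


class TestNipalsFit:
    def test_one_component_univariate_equals_simple_regression(self, rng):
        x = rng.normal(size=30)
        y = 3.0 * x + rng.normal(size=30)
        res = fit_plsr(x[:, None], y, 1)
        slope = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        assert res.coef[0] == pytest.approx(slope, rel=1e-10)

    @pytest.mark.parametrize("n, p", [(12, 3), (20, 8), (9, 5)])
    def test_full_rank_predictions_equal_ols(self, rng, n, p):
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        res = fit_plsr(X, y, p)
        np.testing.assert_allclose(res.fittedvalues, ols_fitted(X, y), rtol=1e-8)

    def test_matches_sklearn_nipals_below_full_rank(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(20, 50))
        y = X[:, :5] @ rng.normal(size=5) + 0.1 * rng.normal(size=20)
        for a in (1, 3, 6):
            res = fit_plsr(X, y, a)
            sk = sklearn.PLSRegression(n_components=a, scale=False).fit(
                X, y.reshape(-1, 1)
            )
            np.testing.assert_allclose(
                res.predict(X), sk.predict(X).ravel(), rtol=1e-8, atol=1e-10
            )

    def test_scores_are_mutually_orthogonal(self, rng):
        X = rng.normal(size=(25, 40))
        y = rng.normal(size=25)
        res = fit_plsr(X, y, 6)
        G = res.x_scores.T @ res.x_scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) <= 1e-8 * np.max(np.diag(G))

    def test_deflation_reconstructs_x_with_orthogonal_residual(self, rng):
        X = rng.normal(size=(15, 12))
        y = rng.normal(size=15)
        res = fit_plsr(X, y, 5)
        Xc = X - res.x_mean
        residual = Xc - res.x_scores @ res.x_loadings.T
        np.testing.assert_allclose(
            res.x_scores @ res.x_loadings.T + residual, Xc, atol=1e-12
        )
        assert np.max(np.abs(res.x_scores.T @ residual)) < 1e-8

    def test_training_rmsep_non_increasing_in_components(self, rng):
        X = rng.normal(size=(30, 20))
        y = X @ rng.normal(size=20) + rng.normal(size=30)
        res = fit_plsr(X, y, 8)
        errs = [
            np.sqrt(np.mean((res.predict(X, a) - y) ** 2))
            for a in range(1, res.n_components + 1)
        ]
        assert np.all(np.diff(errs) <= 1e-10)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_plsr(rng.normal(size=(10, 4)), np.ones(10), 2)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_plsr(rng.normal(size=(5, 3)), rng.normal(size=5), 5)

    def test_summary_mentions_components(self, rng):
        res = fit_plsr(rng.normal(size=(10, 4)), rng.normal(size=10), 2)
        assert "Components" in res.summary()


class TestMetrics:
    def test_perfect_predictions_give_zero_rmsep_and_unit_r2(self, rng):
        X = rng.normal(size=(12, 4))
        beta = rng.normal(size=4)
        y = X @ beta
        res = fit_plsr(X, y, 4)
        assert rmsep(res, X, y) == pytest.approx(0.0, abs=1e-10)
        assert r_squared(res, X, y) == pytest.approx(1.0)

    def test_constant_offset_rmsep_is_the_offset(self, rng):
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        res = fit_plsr(X, y, 3)
        assert rmsep(res, X, y + 0.7) == pytest.approx(0.7, abs=1e-8)

    def test_rmsep_hand_computed_three_samples(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y_train = np.array([0.0, 1.0, 2.0])
        res = fit_plsr(X, y_train, 1)  # exact line y = x
        y_test = np.array([1.0, 0.0, 5.0])  # errors 1, 1, 3
        assert rmsep(res, X, y_test) == pytest.approx(np.sqrt(11.0 / 3.0), rel=1e-12)

    def test_r_squared_is_correlation_based(self, rng):
        X = rng.normal(size=(15, 3))
        y = X @ np.array([1.0, 1.0, 1.0])
        res = fit_plsr(X, y, 3)
        # affine distortion of the observations leaves the squared correlation at 1
        assert r_squared(res, X, 2.5 * y - 3.0) == pytest.approx(1.0)

    def test_r_squared_hand_computed_four_samples(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        res = fit_plsr(X, np.array([0.0, 1.0, 2.0, 3.0]), 1)
        obs = np.array([0.0, 2.0, 1.0, 3.0])
        pred = res.predict(X)
        r = np.corrcoef(pred, obs)[0, 1]
        assert r_squared(res, X, obs) == pytest.approx(r * r, rel=1e-12)

    def test_zero_variance_observations_rejected(self, rng):
        X = rng.normal(size=(8, 2))
        res = fit_plsr(X, rng.normal(size=8), 2)
        with pytest.raises(ValueError):
            r_squared(res, X, np.ones(8))

    def test_band_mismatch_rejected(self, rng):
        X = rng.normal(size=(8, 4))
        res = fit_plsr(X, rng.normal(size=8), 2)
        with pytest.raises(BandMismatchError):
            rmsep(res, rng.normal(size=(3, 5)), np.zeros(3))


class TestRepeatedSplitSearch:
    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.normal(size=(20, 15))
        y = X @ rng.normal(size=15) + rng.normal(size=20)
        r1 = repeated_split_search(X, y, n_iterations=25, seed=42)
        r2 = repeated_split_search(X, y, n_iterations=25, seed=42)
        pd.testing.assert_frame_equal(r1.log, r2.log)
        assert r1.best_iteration == r2.best_iteration
        np.testing.assert_array_equal(
            r1.best_results.trained_on, r2.best_results.trained_on
        )

    def test_noise_free_linear_response_is_solved(self, rng):
        X = rng.normal(size=(24, 10))
        y = X @ rng.normal(size=10) + 2.0
        result = repeated_split_search(X, y, n_iterations=5, seed=0)
        assert result.best_rmsep == pytest.approx(0.0, abs=1e-8)
        assert result.best_r_squared == pytest.approx(1.0)

    def test_best_entry_consistent_with_log(self, rng):
        X = rng.normal(size=(16, 12))
        y = X @ rng.normal(size=12) + rng.normal(size=16)
        result = repeated_split_search(X, y, n_iterations=40, seed=3)
        assert result.best_rmsep == result.log.rmsep.min()
        row = result.log.iloc[result.best_iteration]
        assert row.rmsep == result.best_rmsep
        assert row.n_components == result.best_n_components

    def test_half_split_of_48_samples_trains_on_24(self, rng):
        X = rng.normal(size=(48, 30))
        y = X @ rng.normal(size=30)
        result = repeated_split_search(X, y, n_iterations=3, seed=1)
        assert result.n_train == 24
        assert len(result.best_results.trained_on) == 24

    def test_three_latent_directions_need_few_components(self, rng):
        # X built from 3 informative latent directions: the split-averaged
        # held-out RMSEP curve bottoms out at <= 5 components
        n, p = 60, 40
        T = rng.normal(size=(n, 3))
        P = rng.normal(size=(3, p))
        X = T @ P + 0.05 * rng.normal(size=(n, p))
        y = T @ np.array([2.0, -1.0, 0.5]) + 0.1 * rng.normal(size=n)
        curves = []
        for _ in range(10):
            perm = rng.permutation(n)
            train, test = perm[:30], perm[30:]
            res = fit_plsr(X[train], y[train], 10)
            preds = res.predict_path(X[test])
            curves.append(np.sqrt(np.mean((preds - y[test, None]) ** 2, axis=0)))
        errs = np.mean(curves, axis=0)
        assert int(np.argmin(errs)) + 1 <= 5

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            repeated_split_search(rng.normal(size=(3, 5)), np.arange(3.0), 5)


class TestPredictTimeseries:
    def make_matrix(self, rng, n=10, p=6):
        ann = make_annotations(n // 2, n - n // 2)
        wl = 550.0 + 4.77 * np.arange(p)
        return SpectraMatrix(rng.normal(size=(n, p)), wl, ann)

    def test_training_rows_reproduce_training_fit(self, rng):
        m = self.make_matrix(rng)
        y = m.values @ rng.normal(size=6)
        res = PLSModel.from_spectra(m, y).fit(4)
        out = predict_timeseries(res, m)
        np.testing.assert_allclose(out["prediction"].to_numpy(), res.fittedvalues)
        assert list(out.columns[:4]) == ["genotype", "treatment", "day", "replicate"]

    def test_duplicated_rows_get_identical_predictions(self, rng):
        m = self.make_matrix(rng)
        y = m.values @ rng.normal(size=6)
        res = PLSModel.from_spectra(m, y).fit(3)
        doubled = m.select_rows(np.r_[np.arange(10), np.arange(10)])
        out = predict_timeseries(res, doubled)
        np.testing.assert_allclose(
            out["prediction"].to_numpy()[:10], out["prediction"].to_numpy()[10:]
        )

    def test_negative_predictions_flagged_not_clipped(self, rng):
        m = self.make_matrix(rng)
        y = m.values @ rng.normal(size=6) - 100.0  # strongly negative response
        res = PLSModel.from_spectra(m, y).fit(2)
        out = predict_timeseries(res, m)
        assert out["negative"].any()
        assert (out.loc[out.negative, "prediction"] < 0).all()

    def test_band_mismatch_rejected(self, rng):
        m = self.make_matrix(rng, p=6)
        y = m.values @ rng.normal(size=6)
        res = PLSModel.from_spectra(m, y).fit(2)
        other = self.make_matrix(rng, p=8)
        with pytest.raises(BandMismatchError):
            predict_timeseries(res, other)


def test_model_json_round_trip(tmp_path, rng):
    ann = make_annotations(5, 5)
    wl = 550.0 + 4.77 * np.arange(12)
    m = SpectraMatrix(rng.normal(size=(10, 12)), wl, ann)
    y = m.values @ rng.normal(size=12)
    result = repeated_split_search(m, y, n_iterations=5, max_components=4, seed=9)
    path = tmp_path / "model.json"
    save_model(result, path, metadata={"ion": "Na"})
    snapshot = load_model(path)
    np.testing.assert_allclose(
        snapshot.predict(m.values),
        result.best_results.predict(m.values),
        rtol=1e-12,
    )
    assert snapshot.metadata["ion"] == "Na"
    np.testing.assert_allclose(snapshot.wavelengths_nm, wl)
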