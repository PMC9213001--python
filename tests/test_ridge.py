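"""Ridge core: lag matrices, CV machinery, dereverberation and STRF fits."""

import numpy as np
import pytest

from revadapt.cochlea import Cochleagram
from revadapt.ridge import (
    DereverbModel,
    FitConfig,
    Kernel,
    ResponseSeries,
    build_lag_matrix,
    contiguous_folds,
    fit_dereverb,
    fit_ridge_cv,
    fit_strf,
    mse_reduction,
    ridge_solve,
)

TINY_GRID = tuple(np.geomspace(1e-8, 1e3, 16))


def _coch(values):
    values = np.asarray(values, dtype=float)
    return Cochleagram(
        values=values,
        channel_centers=np.geomspace(400.0, 19000.0, values.shape[0]),
        bin_duration=0.01,
    )


class TestLagMatrix:
    def test_hmax_one_is_transpose(self, rng):
        v = rng.standard_normal((4, 50))
        np.testing.assert_array_equal(build_lag_matrix(v, 1), v.T)

    def test_causal_zero_padding_at_start(self, rng):
        v = rng.standard_normal((3, 30))
        X = build_lag_matrix(v, 5).reshape(30, 3, 5)
        # at the first bin, every lag beyond the current bin is zero
        assert np.all(X[0, :, 1:] == 0)
        np.testing.assert_array_equal(X[0, :, 0], v[:, 0])
        # at bin t, lag h holds x[:, t-h]
        np.testing.assert_array_equal(X[7, :, 3], v[:, 4])

    def test_constant_input_gives_constant_interior_rows(self):
        v = np.full((2, 20), 3.25)
        X = build_lag_matrix(v, 4)
        interior = X[4:]
        assert np.all(interior == 3.25)

    def test_hmax_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            build_lag_matrix(np.zeros((2, 5)), 6)


class TestFolds:
    def test_partition_is_exact_and_disjoint(self):
        folds = contiguous_folds(103, 10)
        cat = np.concatenate(folds)
        assert cat.size == 103
        np.testing.assert_array_equal(np.sort(cat), np.arange(103))
        # contiguity
        for f in folds:
            np.testing.assert_array_equal(np.diff(f), 1)


class TestRidgeSolve:
    def test_matches_closed_form_oracle(self, rng):
        X = rng.standard_normal((200, 60))
        y = rng.standard_normal(200)
        lam = 4.2
        w, b = ridge_solve(X, y, lam, standardize=False)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w_oracle = np.linalg.solve(Xc.T @ Xc + lam * np.eye(60), Xc.T @ yc)
        assert np.abs(w - w_oracle).max() / np.abs(w_oracle).max() < 1e-8

    def test_training_mse_monotone_in_lambda(self, rng):
        X = rng.standard_normal((120, 30))
        y = X @ rng.standard_normal(30) + 0.3 * rng.standard_normal(120)
        prev = -np.inf
        for lam in [1e-4, 1e-2, 1.0, 1e2, 1e4]:
            w, b = ridge_solve(X, y, lam)
            mse = np.mean((X @ w + b - y) ** 2)
            assert mse >= prev - 1e-12
            prev = mse


class TestFitRidgeCV:
    def test_extreme_shrinkage_predicts_mean(self, rng):
        X = rng.standard_normal((150, 20))
        y = rng.standard_normal(150)
        w, b, lam = fit_ridge_cv(X, y, FitConfig(lambda_grid=(1e9,)))
        assert np.abs(w).max() < 1e-6
        assert b == pytest.approx(y.mean(), abs=1e-6)

    def test_planted_solution_recovered(self, rng):
        v = rng.standard_normal((5, 800))
        X = build_lag_matrix(v, 4)
        w_true = rng.standard_normal(20)
        y = X @ w_true + 1.3
        w, b, lam = fit_ridge_cv(X, y, FitConfig(h_max=4, lambda_grid=TINY_GRID))
        assert np.abs(w - w_true).max() < 1e-4
        assert b == pytest.approx(1.3, abs=1e-4)

    def test_constant_target_degenerates_cleanly(self, rng):
        X = rng.standard_normal((100, 10))
        w, b, lam = fit_ridge_cv(X, np.full(100, 2.5), FitConfig())
        assert np.all(w == 0)
        assert b == 2.5

    def test_constant_target_shift_moves_only_bias(self, rng):
        X = rng.standard_normal((200, 15))
        y = X @ rng.standard_normal(15) + 0.2 * rng.standard_normal(200)
        cfg = FitConfig(lambda_grid=(1.0,))
        w0, b0, _ = fit_ridge_cv(X, y, cfg)
        w1, b1, _ = fit_ridge_cv(X, y + 7.0, cfg)
        np.testing.assert_allclose(w0, w1, atol=1e-10)
        assert b1 - b0 == pytest.approx(7.0, abs=1e-10)


class TestDereverbFit:
    def test_identity_mapping_recovers_delta_kernels(self, rng):
        v = rng.standard_normal((6, 500))
        coch = _coch(v)
        model = fit_dereverb(coch, coch, FitConfig(h_max=3, lambda_grid=TINY_GRID))
        for i, k in enumerate(model.kernels):
            assert k.weights[i, 0] == pytest.approx(1.0, abs=1e-4)
            others = k.weights.copy()
            others[i, 0] = 0.0
            assert np.abs(others).max() < 1e-4

    def test_mismatched_grids_rejected(self, rng):
        a = _coch(rng.standard_normal((6, 100)))
        b = _coch(rng.standard_normal((6, 90)))
        with pytest.raises(ValueError):
            fit_dereverb(a, b)

    def test_mse_reduction_trivial_cases(self, rng):
        def identity_model(bias):
            kernels = []
            for i in range(4):
                w = np.zeros((4, 2))
                w[i, 0] = 1.0
                kernels.append(Kernel(weights=w, bias=bias))
            return DereverbModel(kernels=kernels)

        v = rng.standard_normal((4, 200))
        reverb = _coch(v)
        anech = _coch(v + 1.0)
        # prediction == reverberant input -> no reduction
        assert mse_reduction(identity_model(0.0), reverb, anech) == pytest.approx(0.0)
        # prediction == anechoic target -> full reduction
        assert mse_reduction(identity_model(1.0), reverb, anech) == pytest.approx(1.0)

    def test_zero_baseline_rejected(self, rng):
        v = rng.standard_normal((4, 100))
        coch = _coch(v)
        model = fit_dereverb(coch, coch, FitConfig(h_max=2, lambda_grid=(1.0,)))
        with pytest.raises(ValueError, match="baseline"):
            mse_reduction(model, coch, coch)


class TestSTRF:
    def test_planted_strf_recovered_noiseless(self, rng):
        v = rng.standard_normal((8, 900))
        coch = _coch(v)
        w_true = rng.standard_normal((8, 5))
        X = build_lag_matrix(coch, 5)
        y = X @ w_true.ravel() + 0.5
        k = fit_strf(
            coch,
            ResponseSeries("u0", np.clip(y - y.min(), 0, None)),
            FitConfig(h_max=5, lambda_grid=TINY_GRID),
        )
        cos = np.dot(k.weights.ravel(), w_true.ravel()) / (
            np.linalg.norm(k.weights) * np.linalg.norm(w_true)
        )
        assert cos > 0.99

    def test_constant_response_gives_zero_strf(self, rng):
        coch = _coch(rng.standard_normal((6, 300)))
        k = fit_strf(coch, ResponseSeries("u", np.full(300, 0.7)), FitConfig(h_max=4))
        assert np.all(k.weights == 0)
        assert k.bias == pytest.approx(0.7)

    def test_poisson_noise_recovery_correlates_with_truth(self, rng):
        # an LNP-like response with 10 averaged trials still yields the kernel
        v = rng.standard_normal((8, 2000))
        coch = _coch(v)
        w_true = np.zeros((8, 6))
        w_true[3, 1] = 1.0
        w_true[3, 2] = 0.6
        w_true[4, 4] = -0.8
        X = build_lag_matrix(coch, 6)
        rate = np.clip(0.5 + 0.5 * (X @ w_true.ravel()), 0, None)
        counts = rng.poisson(rate, size=(10, rate.size)).mean(axis=0)
        k = fit_strf(coch, ResponseSeries("u", counts), FitConfig(h_max=6))
        r = np.corrcoef(k.weights.ravel(), w_true.ravel())[0, 1]
        assert r > 0.8

    def test_response_length_mismatch_rejected(self, rng):
        coch = _coch(rng.standard_normal((4, 100)))
        with pytest.raises(ValueError):
            fit_strf(coch, ResponseSeries("u", np.zeros(99)))
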