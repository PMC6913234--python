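"""Coarse grid search, fine simplex refinement, and amplitude regression."""

import numpy as np
import pandas as pd
import pytest

from prfpipe.fit import (
    FitConfig,
    GridSpec,
    build_grid,
    coarse_fit,
    fine_fit,
    fit_betas,
    fit_map,
    fit_vertex,
)
from prfpipe.model import PRFParams, predict_timeseries


class TestBuildGrid:
    def test_default_grid_has_7650_candidates(self):
        assert GridSpec().n_candidates == 7650

    def test_grid_predictions_and_flags(self, movie50, hrf, grid50):
        assert grid50.predictions.shape == (movie50.n_frames, 7650)
        ok = ~grid50.degenerate
        cols = grid50.predictions[:, ok]
        assert np.allclose(cols.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(cols.std(axis=0), 1.0, atol=1e-10)

    def test_singleton_grid_matches_predict_timeseries(self, movie50, hrf):
        spec = GridSpec(
            n_angles=1,
            n_eccentricities=1,
            ecc_range=(2.0, 2.0),
            n_sigmas=1,
            sigma_range=(1.0, 1.0),
        )
        grid = build_grid(spec, movie50, hrf)
        assert grid.n_candidates == 1
        direct = predict_timeseries(PRFParams(2.0, 0.0, 1.0), movie50, hrf)
        np.testing.assert_allclose(grid.predictions[:, 0], direct, atol=1e-10)

    def test_far_outside_candidates_flagged_degenerate(self, movie50, hrf):
        spec = GridSpec(
            n_angles=2,
            n_eccentricities=2,
            ecc_range=(15.0, 25.0),  # beyond radius + 2σ for σ ≤ 2
            n_sigmas=2,
            sigma_range=(0.5, 2.0),
        )
        grid = build_grid(spec, movie50, hrf)
        assert grid.degenerate.all()
        assert np.isnan(grid.predictions).all()

    def test_grid_build_deterministic(self, movie50, hrf, small_grid_spec):
        a = build_grid(small_grid_spec, movie50, hrf)
        b = build_grid(small_grid_spec, movie50, hrf)
        assert np.array_equal(a.params, b.params)
        assert np.array_equal(a.predictions, b.predictions, equal_nan=True)


class TestCoarseFit:
    def test_self_consistency_on_grid_candidate(self, movie50, hrf, grid50):
        idx = 3000
        assert not grid50.degenerate[idx]
        res = coarse_fit(grid50.predictions[:, idx], grid50)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            [res.params.x0, res.params.y0, res.params.sigma], grid50.params[idx]
        )

    def test_argmax_matches_exhaustive_loop(self, movie50, hrf, small_grid_spec):
        grid = build_grid(small_grid_spec, movie50, hrf)
        rng = np.random.default_rng(7)
        truth = predict_timeseries(PRFParams(1.7, -2.9, 1.3), movie50, hrf)
        obs = truth + rng.normal(0, 1.0, truth.shape)
        res = coarse_fit(obs, grid)
        best_r, best_idx = -np.inf, -1
        for c in range(grid.n_candidates):
            if grid.degenerate[c]:
                continue
            r = np.corrcoef(obs, grid.predictions[:, c])[0, 1]
            if r > best_r:
                best_r, best_idx = r, c
        np.testing.assert_allclose(
            [res.params.x0, res.params.y0, res.params.sigma], grid.params[best_idx]
        )
        assert res.r_squared == pytest.approx(best_r**2, abs=1e-12)

    def test_tie_breaks_to_first_candidate(self, movie50, hrf):
        spec = GridSpec(
            n_angles=1,
            n_eccentricities=1,
            ecc_range=(2.0, 2.0),
            n_sigmas=2,
            sigma_range=(1.0, 1.0),  # two identical candidates
        )
        grid = build_grid(spec, movie50, hrf)
        res = coarse_fit(grid.predictions[:, 1], grid)
        np.testing.assert_allclose(
            [res.params.x0, res.params.y0, res.params.sigma], grid.params[0]
        )

    def test_degenerate_observed_fails(self, grid50):
        res = coarse_fit(np.zeros(grid50.predictions.shape[0]), grid50)
        assert res.params is None and not res.passed_gate


class TestFineFit:
    def test_noiseless_truth_is_a_fixed_point(self, movie50, hrf):
        truth = PRFParams(2.0, 1.0, 1.0)
        obs = predict_timeseries(truth, movie50, hrf)
        res = fine_fit(obs, truth, movie50, hrf)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert abs(res.params.x0 - truth.x0) < 1e-3
        assert abs(res.params.y0 - truth.y0) < 1e-3
        assert abs(res.params.sigma - truth.sigma) < 1e-3

    def test_off_grid_truth_recovered(self, movie50, hrf, grid50):
        truth = PRFParams(1.23, -2.41, 0.87)
        obs = predict_timeseries(truth, movie50, hrf)
        init = coarse_fit(obs, grid50).params
        res = fine_fit(obs, init, movie50, hrf)
        assert res.stage == "fine"
        assert abs(res.params.x0 - truth.x0) < 0.05
        assert abs(res.params.y0 - truth.y0) < 0.05
        assert abs(res.params.sigma - truth.sigma) < 0.05

    def test_fine_never_below_coarse(self, movie50, hrf, grid50):
        rng = np.random.default_rng(8)
        truth = predict_timeseries(PRFParams(-2.0, 0.5, 1.5), movie50, hrf)
        obs = truth + rng.normal(0, 2.0, truth.shape)
        coarse = coarse_fit(obs, grid50)
        fine = fine_fit(obs, coarse.params, movie50, hrf)
        assert fine.r_squared >= coarse.r_squared - 1e-12

    def test_affine_transform_of_observed_changes_nothing(self, movie50, hrf, grid50):
        rng = np.random.default_rng(9)
        truth = predict_timeseries(PRFParams(0.8, 2.2, 0.9), movie50, hrf)
        obs = truth + rng.normal(0, 1.5, truth.shape)
        a = fit_vertex(obs, grid50, movie50, hrf)
        b = fit_vertex(3.7 * obs - 2.0, grid50, movie50, hrf)
        for key in ("x0", "y0", "sigma", "r2"):
            assert a[key] == pytest.approx(b[key], abs=1e-6)


class TestFitBetas:
    def test_exact_line(self):
        pred = np.sin(np.linspace(0, 8, 100))
        beta1, beta0 = fit_betas(2.0 * pred + 3.0, pred)
        assert beta1 == pytest.approx(2.0, abs=1e-10)
        assert beta0 == pytest.approx(3.0, abs=1e-10)

    def test_orthogonal_observed_gives_zero_amplitude(self):
        t = np.arange(100)
        pred = np.sin(2 * np.pi * t / 10)
        obs = np.cos(2 * np.pi * t / 10)
        beta1, _ = fit_betas(obs, pred)
        assert abs(beta1) < 1e-10

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(10)
        pred = rng.normal(size=200)
        obs = rng.normal(size=200)
        beta1, beta0 = fit_betas(obs, pred)
        Xd = np.column_stack([pred, np.ones(200)])
        ref = np.linalg.solve(Xd.T @ Xd, Xd.T @ obs)
        assert beta1 == pytest.approx(ref[0], abs=1e-10)
        assert beta0 == pytest.approx(ref[1], abs=1e-10)


class TestFitMap:
    def test_noiseless_vertices_fit_perfectly(self, movie50, hrf, grid50):
        params = [
            PRFParams(x, y, s)
            for x, y, s in [(1.1, 0.4, 0.6), (-2.3, 1.8, 1.4), (0.2, -3.7, 2.2)]
        ]
        data = np.column_stack(
            [predict_timeseries(p, movie50, hrf) for p in params]
        )
        fits = fit_map(data, grid50, movie50, hrf)
        assert len(fits) == 3
        assert (fits["stage"] == "fine").all()
        assert (fits["r2"] > 0.999).all()

    def test_pure_noise_vertices_stay_below_display_threshold(
        self, movie50, hrf, grid50
    ):
        rng = np.random.default_rng(11)
        data = rng.normal(size=(movie50.n_frames, 10))
        fits = fit_map(data, grid50, movie50, hrf)
        assert len(fits) == 10
        assert (fits["r2"] < 0.10).sum() >= 6

    def test_degenerate_columns_fail_cleanly(self, movie50, hrf, grid50):
        data = np.zeros((movie50.n_frames, 2))
        data[:, 1] = np.nan
        fits = fit_map(data, grid50, movie50, hrf)
        assert (fits["stage"] == "failed").all()
        assert fits["x0"].isna().all()

    def test_betas_recover_simulated_gain_and_offset(self, movie50, hrf, grid50):
        truth = PRFParams(1.0, 1.0, 1.0)
        pred = predict_timeseries(truth, movie50, hrf)
        data = (4.2 * pred + 0.7)[:, None]
        fits = fit_map(data, grid50, movie50, hrf)
        assert fits.loc[0, "beta1"] == pytest.approx(4.2, rel=1e-3)
        assert fits.loc[0, "beta0"] == pytest.approx(0.7, abs=1e-2)
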