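"""Mesh metrics: polygon areas, CMF, smoothing, bins, map comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from prfpipe.simulate import make_flat_mesh
from prfpipe.surface import (
    RetinoMesh,
    bin_summarize,
    circular_corr,
    cmf_map,
    compare_maps,
    neighbor_polygon_area,
    smooth_map,
)


class TestPolygonArea:
    def test_unit_square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert neighbor_polygon_area(pts) == pytest.approx(1.0)

    def test_collinear_points_zero(self):
        pts = np.array([[0, 0], [1, 1], [2, 2]], dtype=float)
        assert neighbor_polygon_area(pts) == pytest.approx(0.0)

    def test_fewer_than_three_points_undefined(self):
        assert np.isnan(neighbor_polygon_area(np.array([[0.0, 0.0], [1.0, 1.0]])))

    @given(st.integers(0, 1000))
    def test_matches_triangle_fan_oracle(self, seed):
        """Shoelace area of a polygon star-shaped about the origin equals
        its fan decomposition into origin-apex triangles."""
        rng = np.random.default_rng(seed)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 6))
        radii = rng.uniform(0.5, 2.0, 6)
        pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        fan = 0.0
        for i in range(6):
            b, c = pts[i], pts[(i + 1) % 6]
            fan += 0.5 * (b[0] * c[1] - b[1] * c[0])  # signed origin triangle
        assert neighbor_polygon_area(pts) == pytest.approx(abs(fan), abs=1e-12)


class TestCMF:
    def test_constant_magnification_recovered_exactly(self):
        mesh = make_flat_mesh(grid_n=10, magnification=2.0)
        out = cmf_map(mesh)
        interior = out["interior"]
        np.testing.assert_allclose(out.loc[interior, "cmf"], 2.0, atol=1e-9)
        assert not out.loc[~interior, "cmf"].notna().any()

    def test_homogeneity_under_cortical_scaling(self):
        mesh = make_flat_mesh(grid_n=8, magnification=2.0)
        scaled = RetinoMesh(mesh.vertices * 3.0, mesh.triangles, mesh.fits)
        a = cmf_map(mesh)["cmf"]
        b = cmf_map(scaled)["cmf"]
        ok = a.notna()
        np.testing.assert_allclose(b[ok], 3.0 * a[ok], rtol=1e-9)

    def test_log_polar_patch_matches_analytic_curve(self):
        mesh = make_flat_mesh(
            grid_n=14, magnification={"k": 12.0, "a": 0.75}, spacing_mm=1.0,
            origin_mm=(2.0, 0.0),
        )
        out = cmf_map(mesh)
        true = mesh.extras["true_cmf"]
        sel = out["interior"].to_numpy() & np.isfinite(out["cmf"].to_numpy())
        rel = np.abs(out.loc[sel, "cmf"].to_numpy() - true[sel]) / true[sel]
        assert np.max(rel) < 0.05
        # magnification falls toward the periphery on a log-polar patch
        ecc = np.hypot(mesh.fits["x0"], mesh.fits["y0"]).to_numpy()[sel]
        cmf = out.loc[sel, "cmf"].to_numpy()
        assert np.corrcoef(ecc, cmf)[0, 1] < -0.8

    def test_zero_visual_area_flagged(self):
        mesh = make_flat_mesh(grid_n=6, magnification=1.0)
        fits = mesh.fits.copy()
        fits["x0"] = 1.0  # every pRF collapses to one point
        fits["y0"] = 1.0
        out = cmf_map(mesh, fits)
        assert out["cmf"].isna().all()


class TestSmoothMap:
    def test_constant_map_unchanged(self):
        mesh = make_flat_mesh(grid_n=8)
        out = smooth_map(mesh, np.full(mesh.n_vertices, 2.5), fwhm_mm=3.0)
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_zero_fwhm_is_identity(self):
        mesh = make_flat_mesh(grid_n=8)
        values = np.arange(mesh.n_vertices, dtype=float)
        np.testing.assert_allclose(smooth_map(mesh, values, 0.0), values, atol=1e-9)

    def test_impulse_matches_direct_weight_matrix(self):
        mesh = make_flat_mesh(grid_n=9)
        values = np.zeros(mesh.n_vertices)
        centre = 4 * 9 + 4
        values[centre] = 1.0
        fwhm = 3.0
        out = smooth_map(mesh, values, fwhm)
        sd = fwhm / (2 * np.sqrt(2 * np.log(2)))
        xy = mesh.patch_xy()
        d = np.linalg.norm(xy - xy[centre], axis=1)
        w = np.exp(-(d**2) / (2 * sd**2))
        w[d > 3 * sd] = 0.0
        dall = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        wall = np.exp(-(dall**2) / (2 * sd**2))
        wall[dall > 3 * sd] = 0.0
        expected = w / wall.sum(axis=1)
        np.testing.assert_allclose(out, expected, atol=1e-9)
        assert (out > 0).sum() > 1  # the impulse spreads

    def test_nan_neighbours_excluded_with_renormalisation(self):
        mesh = make_flat_mesh(grid_n=6)
        values = np.full(mesh.n_vertices, 4.0)
        values[0] = np.nan
        out = smooth_map(mesh, values, 3.0)
        np.testing.assert_allclose(out, 4.0, atol=1e-12)


class TestBinSummarize:
    def test_mean_of_small_bin(self):
        out = bin_summarize(
            np.array([1.0, 1.1, 1.2]), np.array([1.0, 2.0, 3.0]),
            statistic="mean", r2_threshold=None, n_boot=200,
        )
        row = out[out["n"] > 0].iloc[0]
        assert row["value"] == pytest.approx(2.0)
        assert row["bin_lo"] == 0.5 and row["bin_hi"] == 1.5

    def test_low_r2_vertices_excluded(self):
        ecc = np.array([1.0, 1.0])
        val = np.array([1.0, 100.0])
        r2 = np.array([0.5, 0.10])
        out = bin_summarize(ecc, val, r_squared=r2, r2_threshold=0.15, n_boot=100)
        assert out[out["n"] > 0].iloc[0]["value"] == pytest.approx(1.0)

    def test_constant_bin_has_zero_width_ci(self):
        out = bin_summarize(
            np.full(20, 3.0), np.full(20, 7.0), r2_threshold=None, n_boot=300
        )
        row = out[out["n"] > 0].iloc[0]
        assert row["ci_low"] == row["ci_high"] == row["value"] == 7.0

    def test_half_open_bins_final_bin_closed(self):
        ecc = np.array([1.5, 9.5])
        val = np.array([1.0, 2.0])
        out = bin_summarize(ecc, val, r2_threshold=None, n_boot=50)
        assert out.iloc[0]["n"] == 0  # 1.5 belongs to [1.5, 2.5)
        assert out.iloc[1]["n"] == 1
        assert out.iloc[-1]["n"] == 1  # 9.5 included in the closed final bin

    def test_empty_bins_flagged(self):
        out = bin_summarize(np.array([1.0]), np.array([1.0]), r2_threshold=None, n_boot=50)
        assert out["empty"].sum() == len(out) - 1


class TestCircularCorr:
    def test_identity_and_rotation_invariance(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(0, 2 * np.pi, 200)
        assert circular_corr(a, a) == pytest.approx(1.0, abs=1e-12)
        assert circular_corr(a, a + 1.234) == pytest.approx(1.0, abs=1e-9)

    def test_independent_angles_near_zero(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(0, 2 * np.pi, 1000)
        b = rng.uniform(0, 2 * np.pi, 1000)
        assert abs(circular_corr(a, b)) < 0.07

    def test_matches_naive_pairwise_loop(self):
        rng = np.random.default_rng(14)
        a = rng.uniform(0, 2 * np.pi, 40)
        b = rng.uniform(0, 2 * np.pi, 40)
        num = den_a = den_b = 0.0
        for i in range(40):
            for j in range(40):
                sa = np.sin(a[i] - a[j])
                sb = np.sin(b[i] - b[j])
                num += sa * sb
                den_a += sa**2
                den_b += sb**2
        ref = num / np.sqrt(den_a * den_b)
        assert circular_corr(a, b) == pytest.approx(ref, abs=1e-12)

    def test_too_few_pairs_undefined(self):
        assert np.isnan(circular_corr(np.array([0.1, 0.2]), np.array([0.3, 0.4])))


def _random_fit_table(rng, n):
    ecc = np.sqrt(rng.uniform(0.25, 64.0, n))
    ang = rng.uniform(0, 2 * np.pi, n)
    return pd.DataFrame(
        {
            "vertex_id": np.arange(n),
            "x0": ecc * np.cos(ang),
            "y0": ecc * np.sin(ang),
            "sigma": rng.uniform(0.3, 3.0, n),
            "r2": rng.uniform(0, 1, n),
        }
    )


class TestCompareMaps:
    def test_map_against_itself(self):
        fits = _random_fit_table(np.random.default_rng(15), 300)
        out = compare_maps(fits, fits)
        assert out["polar_r"] == pytest.approx(1.0, abs=1e-9)
        assert out["ecc_rho"] == pytest.approx(1.0, abs=1e-12)

    def test_threshold_must_hold_in_both_maps(self):
        fits = _random_fit_table(np.random.default_rng(16), 50)
        other = fits.copy()
        other.loc[0:9, "r2"] = 0.0  # drop 10 vertices in one map only
        out = compare_maps(fits, other, r2_threshold=0.1)
        both = ((fits["r2"] > 0.1) & (other["r2"] > 0.1)).sum()
        assert out["n_common"] == both

    def test_shuffled_map_decorrelates(self):
        rng = np.random.default_rng(17)
        fits = _random_fit_table(rng, 1000)
        fits["r2"] = 0.5
        shuffled = fits.copy()
        perm = rng.permutation(1000)
        for col in ("x0", "y0"):
            shuffled[col] = fits[col].to_numpy()[perm]
        out = compare_maps(fits, shuffled)
        assert abs(out["polar_r"]) < 0.07
        assert abs(out["ecc_rho"]) < 0.07

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(18)
        a = _random_fit_table(rng, 200)
        b = _random_fit_table(rng, 200)
        ab = compare_maps(a, b)
        ba = compare_maps(b, a)
        assert ab["polar_r"] == pytest.approx(ba["polar_r"], abs=1e-12)
        assert ab["ecc_rho"] == pytest.approx(ba["ecc_rho"], abs=1e-12)
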