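"""Preprocessing: outlier removal, progressive TIN ground filtering,
height normalization, Savitzky-Golay smoothing and quadratic
co-registration."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from canopyfuse import (
    denoise,
    filter_ground,
    fit_quadratic_registration,
    inject_gross_errors,
    normalize_heights,
    smooth_spectra,
)
from canopyfuse.containers import GROUND, NOISE, VEGETATION
from canopyfuse.preprocess import register_cube

from conftest import make_cloud


class TestDenoise:
    def test_clean_cloud_essentially_untouched(self):
        # without gross errors the kNN-distance tail of a homogeneous
        # cloud is thin: a wide threshold keeps every point, the default
        # threshold trims well under 1%
        rng = np.random.default_rng(8)
        n = 5000
        cloud = make_cloud(rng.uniform(0, 30, n), rng.uniform(0, 30, n),
                           rng.uniform(0, 1, n))
        wide = denoise(cloud, sd_multiplier=5.0)
        assert (wide.classification == NOISE).sum() == 0
        default = denoise(cloud)
        assert (default.classification == NOISE).mean() < 0.01

    def test_recovers_injected_gross_errors(self, sparse_scene):
        noisy = inject_gross_errors(sparse_scene["cloud"], 10, 5, seed=99)
        out = denoise(noisy)
        injected = (out.source == "noise_high") | (out.source == "noise_low")
        flagged = out.classification == NOISE
        assert (flagged & injected).sum() >= 14
        # false-positive rate on genuine returns stays negligible
        assert (flagged & ~injected).sum() <= 0.001 * len(out)

    def test_extreme_isolated_point_flagged(self):
        rng = np.random.default_rng(0)
        n = 500
        cloud = make_cloud(rng.uniform(0, 20, n), rng.uniform(0, 20, n),
                           rng.uniform(0, 2, n))
        cloud.x[0], cloud.y[0], cloud.z[0] = 10.0, 10.0, 100.0
        out = denoise(cloud)
        assert out.classification[0] == NOISE

    def test_partition_not_transformation(self, sparse_scene):
        cloud = sparse_scene["cloud"]
        out = denoise(cloud)
        assert np.array_equal(out.x, cloud.x)
        assert np.array_equal(out.z, cloud.z)

    def test_too_few_points_warns_and_noops(self):
        cloud = make_cloud([0, 1], [0, 1], [0, 1])
        with pytest.warns(UserWarning):
            out = denoise(cloud, k_neighbors=10)
        assert (out.classification == NOISE).sum() == 0


class TestFilterGround:
    def test_flat_terrain_all_ground(self):
        rng = np.random.default_rng(1)
        n = 2000
        cloud = make_cloud(rng.uniform(0, 40, n), rng.uniform(0, 40, n),
                           np.full(n, 5.0) + rng.normal(0, 0.005, n))
        out = filter_ground(cloud)
        assert (out.classification == GROUND).mean() > 0.99

    def test_point_far_above_tin_never_added(self):
        rng = np.random.default_rng(2)
        n = 1000
        x = rng.uniform(0, 30, n)
        y = rng.uniform(0, 30, n)
        z = np.zeros(n)
        x[0], y[0], z[0] = 15.0, 15.0, 10.0
        out = filter_ground(make_cloud(x, y, z))
        assert out.classification[0] == VEGETATION

    def test_recovers_synthetic_ground_labels(self, sparse_scene):
        out = filter_ground(denoise(sparse_scene["cloud"]))
        ground = out.classification == GROUND
        tagged = out.source == "ground"
        crown = np.char.startswith(out.source.astype(str), "crown")
        assert (ground & tagged).sum() / tagged.sum() >= 0.95
        assert (ground & crown).sum() / crown.sum() <= 0.02

    def test_partition_preserves_coordinates(self, sparse_scene):
        cloud = sparse_scene["cloud"]
        out = filter_ground(denoise(cloud))
        assert np.array_equal(out.x, cloud.x)
        assert np.array_equal(out.z, cloud.z)


class TestNormalizeHeights:
    def test_constant_offset_terrain(self):
        rng = np.random.default_rng(3)
        n = 800
        x, y = rng.uniform(0, 30, n), rng.uniform(0, 30, n)
        z = np.full(n, 5.0)
        z[0] = 12.0  # one elevated point
        cloud = make_cloud(x, y, z)
        cloud.classification[:] = GROUND
        cloud.classification[0] = VEGETATION
        out = normalize_heights(cloud)
        assert out.hag[0] == pytest.approx(7.0, abs=1e-6)

    def test_ground_points_near_zero(self, processed_scene):
        cloud = processed_scene["cloud_norm"]
        g = cloud.classification == GROUND
        assert np.nanmax(np.abs(cloud.hag[g])) < 0.05

    def test_tree_height_recovered(self, processed_scene):
        cloud = processed_scene["cloud_norm"]
        truth = processed_scene["truth"]
        conifers = {"LG"}  # cone crowns: the pulse grid rarely samples the
        # apex point, so H_T is biased low by up to the cone slope times
        # the expected nearest-pulse offset
        for _, s in truth.stems.iterrows():
            sel = cloud.source == f"crown:{int(s.tree_id)}"
            tol = 0.9 if s.species in conifers else 0.5
            assert cloud.hag[sel].max() == pytest.approx(s.height, abs=tol)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        n = 500
        cloud = make_cloud(rng.uniform(0, 20, n), rng.uniform(0, 20, n),
                           rng.uniform(0, 0.01, n))
        cloud.classification[:] = GROUND
        once = normalize_heights(cloud)
        twice = normalize_heights(once)
        assert np.allclose(once.hag, twice.hag)


class TestSmoothSpectra:
    def test_constant_preserved(self):
        s = np.full(300, 0.3)
        assert np.allclose(smooth_spectra(s), s)

    def test_polynomial_of_fit_order_exact(self):
        x = np.arange(100, dtype=float)
        s = 0.2 + 0.01 * x - 3e-5 * x**2
        assert np.allclose(smooth_spectra(s, window=7, polyorder=2), s,
                           atol=1e-10)

    def test_impulse_attenuated_by_center_coefficient(self):
        # independent oracle: the analytic SG center coefficient
        window, poly = 7, 2
        c0 = savgol_coeffs(window, poly)[window // 2]
        assert c0 == pytest.approx(7 / 21)
        s = np.full(101, 0.3)
        s[50] += 0.1
        out = smooth_spectra(s, window=window, polyorder=poly)
        assert out[50] == pytest.approx(0.3 + 0.1 * c0, abs=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(5)
        s1, s2 = rng.random(300), rng.random(300)
        lhs = smooth_spectra(2.0 * s1 + 3.0 * s2)
        rhs = 2.0 * smooth_spectra(s1) + 3.0 * smooth_spectra(s2)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_spectra(np.ones(50), window=6)

    def test_cube_shape_preserved(self, sparse_scene):
        cube = sparse_scene["cube"]
        out = smooth_spectra(cube)
        assert out.data.shape == cube.data.shape
        assert out.data.min() >= 0 and out.data.max() <= 1


class TestQuadraticRegistration:
    @staticmethod
    def _grid(n=5, span=40.0):
        g = np.linspace(0, span, n)
        gx, gy = np.meshgrid(g, g)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def test_identity_pairs(self):
        pts = self._grid()
        t = fit_quadratic_registration(pts, pts)
        assert t.rms == pytest.approx(0.0, abs=1e-10)
        x, y = t(pts[:, 0], pts[:, 1])
        assert np.allclose(x, pts[:, 0]) and np.allclose(y, pts[:, 1])

    def test_recovers_known_quadratic_warp(self):
        pts = self._grid()
        cx = np.array([0.5, 1.01, 0.002, 1e-4, -2e-4, 5e-5])
        cy = np.array([-0.3, -0.001, 0.998, 2e-4, 1e-4, -8e-5])
        from canopyfuse.preprocess import _quad_design

        d = _quad_design(pts[:, 0], pts[:, 1])
        dst = np.column_stack([d @ cx, d @ cy])
        t = fit_quadratic_registration(pts, dst)
        assert np.allclose(t.coef_x, cx, atol=1e-8)
        assert np.allclose(t.coef_y, cy, atol=1e-8)
        assert t.rms == pytest.approx(0.0, abs=1e-8)

    def test_noisy_pairs_rms_within_one_pixel(self):
        rng = np.random.default_rng(7)
        pts = self._grid(6)
        cx = np.array([0.2, 1.0, 0.01, 1e-4, -1e-4, 2e-5])
        cy = np.array([0.1, -0.01, 1.0, -2e-4, 5e-5, 1e-4])
        from canopyfuse.preprocess import _quad_design

        d = _quad_design(pts[:, 0], pts[:, 1])
        dst = np.column_stack([d @ cx, d @ cy]) + rng.normal(0, 0.05,
                                                             (len(pts), 2))
        t = fit_quadratic_registration(pts, dst)
        assert t.rms <= 0.10  # within one 10 cm pixel

    def test_too_few_or_collinear_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic_registration(np.zeros((5, 2)), np.zeros((5, 2)))
        line = np.column_stack([np.arange(8.0), np.arange(8.0)])
        with pytest.raises(ValueError):
            fit_quadratic_registration(line, line)

    def test_register_cube_identity_roundtrip(self, sparse_scene):
        cube = sparse_scene["cube"]
        pts = self._grid(4, span=20.0)
        t = fit_quadratic_registration(pts, pts)
        out = register_cube(cube, t)
        assert np.array_equal(out.data, cube.data)
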