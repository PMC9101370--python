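"""Vegetation indices, LAI regression, cover fractions, resampling."""

import numpy as np
import pytest

from etmap.raster import Affine, Raster
from etmap.raster_prep import (
    SurfaceInputs,
    compute_index,
    fit_lai_model,
    fraction_raster,
    green_mask,
    lai_map,
    resample_to_grid,
    sample_window,
)


def _rgb(r, g, b, shape=(4, 4), res=0.1):
    img = np.zeros((3, *shape))
    img[0], img[1], img[2] = r, g, b
    return Raster(img, Affine.from_origin(0, shape[0] * res, res, res), crs="LOCAL")


class TestIndices:
    def test_g_equals_r_gives_zero(self):
        r = _rgb(0.3, 0.3, 0.1)
        assert np.allclose(compute_index(r, "VI").values, 0.0)
        assert np.allclose(compute_index(r, "VARI").values, 0.0)

    def test_vari_arithmetic(self):
        r = _rgb(0.2, 0.4, 0.1)
        assert np.allclose(compute_index(r, "VARI").values, 0.4)

    def test_vi_arithmetic(self):
        r = _rgb(0.1, 0.3, 0.0)
        assert np.allclose(compute_index(r, "VI").values, 0.5)

    def test_zero_denominator_is_nodata(self):
        r = _rgb(0.1, 0.1, 0.2)  # G+R-B = 0
        assert np.isnan(compute_index(r, "VARI").values).all()

    def test_byte_input_normalized(self):
        byte = _rgb(51, 102, 25)  # /255 -> (0.2, 0.4, 0.098)
        byte.values = byte.values.astype(np.uint8)
        expected = (0.4 - 0.2) / (0.4 + 0.2 - 25 / 255)
        assert np.allclose(compute_index(byte, "VARI").values, expected)

    def test_invariant_to_uniform_scaling(self):
        a = _rgb(0.2, 0.4, 0.1)
        b = _rgb(0.1, 0.2, 0.05)
        for kind in ("VI", "VARI"):
            assert np.allclose(compute_index(a, kind).values, compute_index(b, kind).values)

    def test_band_count_checked(self):
        bad = Raster(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError):
            compute_index(bad, "VI")


class TestLAIModel:
    def test_exact_fit_selects_vari(self):
        vari = np.linspace(0.0, 0.5, 10)
        vi = np.full(10, 0.2) + np.linspace(0, 1e-3, 10)  # nearly constant -> poor fit
        lai = 2.0 * vari + 1.0
        model = fit_lai_model(list(zip(lai, vi, vari)))
        assert model.index_kind == "VARI"
        assert model.slope == pytest.approx(2.0, abs=1e-10)
        assert model.intercept == pytest.approx(1.0, abs=1e-10)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_equal_r2_tie_goes_to_vari(self):
        x = np.linspace(0, 1, 8)
        lai = 3.0 * x + 0.5  # both indices identical -> identical R²
        model = fit_lai_model(list(zip(lai, x, x)))
        assert model.index_kind == "VARI"

    def test_noisy_fit_matches_normal_equations(self):
        rng = np.random.default_rng(9)
        vari = rng.uniform(0, 0.6, 40)
        vi = rng.uniform(0, 0.4, 40)
        lai = 4.0 * vari + 0.3 + rng.normal(0, 0.2, 40)
        model = fit_lai_model(list(zip(lai, vi, vari)))
        X = np.column_stack([vari, np.ones(40)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ lai)
        assert model.slope == pytest.approx(slope, abs=1e-10)
        assert model.intercept == pytest.approx(intercept, abs=1e-10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(10)
        vari = rng.uniform(0, 0.6, 20)
        vi = rng.uniform(0, 0.4, 20)
        lai = 2.0 * vari + 1.0 + rng.normal(0, 0.1, 20)
        m1 = fit_lai_model(list(zip(lai, vi, vari)))
        m2 = fit_lai_model(list(zip(3.0 * lai, vi, vari)))
        assert m2.slope == pytest.approx(3.0 * m1.slope, rel=1e-9)
        assert m2.intercept == pytest.approx(3.0 * m1.intercept, rel=1e-9)
        assert m2.r_squared == pytest.approx(m1.r_squared, abs=1e-12)

    def test_constant_index_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_lai_model([(1.0, 0.2, 0.3), (2.0, 0.2, 0.3)])


class TestLAIMap:
    def _model(self):
        x = np.linspace(0, 1, 5)
        return fit_lai_model(list(zip(2.0 * x + 1.0, x, x)))

    def test_zero_index_gives_intercept(self):
        model = self._model()
        idx = Raster(np.zeros((3, 3)))
        assert np.allclose(lai_map(model, idx).values, 1.0)

    def test_negative_lai_clamped(self):
        model = self._model()
        idx = Raster(np.full((2, 2), -5.0))
        assert np.all(lai_map(model, idx).values == 0.0)

    def test_matches_scalar_oracle_and_propagates_nan(self):
        model = self._model()
        rng = np.random.default_rng(11)
        vals = rng.uniform(-1, 1, (6, 6))
        vals[0, 0] = np.nan
        out = lai_map(model, Raster(vals)).values
        assert np.isnan(out[0, 0])
        expect = np.maximum(model.slope * vals[1:, :] + model.intercept, 0.0)
        assert np.allclose(out[1:, :], expect)

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError, match="fitted"):
            lai_map(self._model(), Raster(np.zeros((2, 2))), index_kind="VI")


class TestGreenMask:
    def test_pure_green_all_true(self):
        r = _rgb(0.1, 0.8, 0.1)
        assert green_mask(r).values.all()

    def test_gray_all_false(self):
        r = _rgb(0.5, 0.5, 0.5)
        assert not green_mask(r).values.any()

    def test_half_scene_fraction(self, rgb_raster):
        mask = green_mask(rgb_raster)
        frac = mask.values.mean()
        assert frac == pytest.approx(0.5, abs=1 / 60)

    def test_automatic_threshold_splits_bimodal_scene(self, rgb_raster):
        mask = green_mask(rgb_raster, threshold=None)
        # the green/gray halves are well separated, auto split finds them
        assert mask.values.mean() == pytest.approx(0.5, abs=0.05)
        assert mask.values[:, :25].mean() > 0.9
        assert mask.values[:, 35:].mean() < 0.1


class TestFractionRaster:
    def _target(self, n=3, res=0.4):
        return Raster(np.zeros((n, n)), Affine.from_origin(0, n * res, res, res), crs="LOCAL")

    def test_all_true_gives_one(self):
        mask = Raster(np.ones((12, 12), np.uint8), Affine.from_origin(0, 1.2, 0.1, 0.1), crs="LOCAL")
        out = fraction_raster(mask, self._target())
        assert np.allclose(out.values, 1.0)

    def test_checkerboard_half(self):
        m = np.indices((12, 12)).sum(0) % 2
        mask = Raster(m.astype(np.uint8), Affine.from_origin(0, 1.2, 0.1, 0.1), crs="LOCAL")
        out = fraction_raster(mask, self._target())
        assert np.allclose(out.values, 0.5)

    def test_random_mask_matches_counting_oracle(self):
        rng = np.random.default_rng(12)
        m = rng.random((12, 12)) < 0.3
        mask = Raster(m.astype(np.uint8), Affine.from_origin(0, 1.2, 0.1, 0.1), crs="LOCAL")
        out = fraction_raster(mask, self._target())
        # 4x4 blocks of the fine mask per target cell
        oracle = m.reshape(3, 4, 3, 4).mean(axis=(1, 3))
        assert np.allclose(out.values, oracle)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        # area-weighted mean equals global fraction
        assert out.values.mean() == pytest.approx(m.mean(), abs=1e-9)

    def test_site_modes(self):
        m = np.zeros((12, 12), np.uint8)
        m[:, :6] = 1
        mask = Raster(m, Affine.from_origin(0, 1.2, 0.1, 0.1), crs="LOCAL")
        f_c, f_g = fraction_raster(mask, self._target(), site_mode="grassland")
        assert np.allclose(f_c.values, 1.0)
        assert np.allclose(f_g.values[:, 0], 1.0) and np.allclose(f_g.values[:, 2], 0.0)
        f_c2, f_g2 = fraction_raster(mask, self._target(), site_mode="cropland")
        assert np.allclose(f_g2.values, 1.0)
        assert np.allclose(f_c2.values, f_g.values)

    def test_crs_mismatch_rejected(self):
        mask = Raster(np.ones((4, 4), np.uint8), Affine.from_origin(0, 1, 0.25, 0.25), crs="EPSG:4326")
        with pytest.raises(ValueError, match="CRS"):
            fraction_raster(mask, self._target())


class TestResample:
    def test_constant_preserved(self):
        src = Raster(np.full((20, 20), 7.0), Affine.from_origin(0, 2, 0.1, 0.1), crs="LOCAL")
        tgt = Raster(np.zeros((5, 5)), Affine.from_origin(0, 2, 0.4, 0.4), crs="LOCAL")
        assert np.allclose(resample_to_grid(src, tgt, "mean").values, 7.0)
        assert np.allclose(resample_to_grid(src, tgt, "nearest").values, 7.0)

    def test_block_mean_oracle_integer_ratio(self):
        rng = np.random.default_rng(13)
        v = rng.normal(size=(20, 20))
        src = Raster(v, Affine.from_origin(0, 2, 0.1, 0.1), crs="LOCAL")
        tgt = Raster(np.zeros((5, 5)), Affine.from_origin(0, 2, 0.4, 0.4), crs="LOCAL")
        out = resample_to_grid(src, tgt, "mean")
        oracle = v.reshape(5, 4, 5, 4).mean(axis=(1, 3))
        assert np.allclose(out.values, oracle, atol=1e-9)

    def test_nearest_keeps_categories(self):
        rng = np.random.default_rng(14)
        v = rng.integers(0, 4, (20, 20))
        src = Raster(v, Affine.from_origin(0, 2, 0.1, 0.1), crs="LOCAL")
        tgt = Raster(np.zeros((7, 7)), Affine.from_origin(0, 2, 2 / 7, 2 / 7), crs="LOCAL")
        out = resample_to_grid(src, tgt, "nearest")
        assert set(np.unique(out.values)) <= set(np.unique(v))

    def test_disjoint_extents_rejected(self):
        src = Raster(np.zeros((4, 4)), Affine.from_origin(0, 1, 0.25, 0.25), crs="LOCAL")
        tgt = Raster(np.zeros((4, 4)), Affine.from_origin(100, 101, 0.25, 0.25), crs="LOCAL")
        with pytest.raises(ValueError, match="disjoint"):
            resample_to_grid(src, tgt, "mean")


class TestSurfaceInputs:
    def test_coregistration_enforced(self):
        t = Affine.from_origin(0, 1, 0.1, 0.1)
        mk = lambda v: Raster(v, t, crs="LOCAL")  # noqa: E731
        good = SurfaceInputs(
            t_rad=mk(np.full((10, 10), 25.0)), lai=mk(np.ones((10, 10))),
            f_c=mk(np.ones((10, 10))), f_g=mk(np.ones((10, 10))),
        )
        assert good.t_rad.same_grid(good.lai)
        with pytest.raises(ValueError, match="co-registered"):
            SurfaceInputs(
                t_rad=mk(np.zeros((10, 10))), lai=mk(np.ones((9, 10))),
                f_c=mk(np.ones((10, 10))), f_g=mk(np.ones((10, 10))),
            )

    def test_bounds_enforced(self):
        t = Affine.from_origin(0, 1, 0.1, 0.1)
        mk = lambda v: Raster(v, t, crs="LOCAL")  # noqa: E731
        with pytest.raises(ValueError, match="f_c"):
            SurfaceInputs(
                t_rad=mk(np.zeros((4, 4))), lai=mk(np.ones((4, 4))),
                f_c=mk(np.full((4, 4), 1.5)), f_g=mk(np.ones((4, 4))),
            )
        with pytest.raises(ValueError, match="lai"):
            SurfaceInputs(
                t_rad=mk(np.zeros((4, 4))), lai=mk(np.full((4, 4), -1.0)),
                f_c=mk(np.ones((4, 4))), f_g=mk(np.ones((4, 4))),
            )


class TestSampleWindow:
    def test_window_mean(self):
        v = np.zeros((10, 10))
        v[4:7, 4:7] = 3.0
        r = Raster(v, Affine.from_origin(0, 1, 0.1, 0.1), crs="LOCAL")
        # world point at the center pixel (5,5); 3x3 window fully inside the patch
        x, y = r.xy(5, 5)
        assert sample_window(r, x, y, size=3) == pytest.approx(3.0)
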