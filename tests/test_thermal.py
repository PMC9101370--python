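"""Pseudo-color codec: key map, attribution, round trips, PPM I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etmap.fixtures import encode_snapshot, make_color_scale
from etmap.raster import Affine, Raster
from etmap.thermal import (
    ColorScale,
    ThermalSnapshot,
    attribute_color,
    decode_snapshot,
    flight_common_range,
    level_to_temperature,
    mosaic_to_temperature_raster,
    read_ppm,
    rescale_snapshot,
    rgb_to_value,
    temperature_to_level,
    write_ppm,
)

HALF_STEP = lambda span, n=239: span / (2 * (n - 1))  # noqa: E731


class TestKeyMap:
    @pytest.mark.parametrize(
        "rgb,key",
        [
            ((0, 0, 0), 0),
            ((0, 0, 1), 255),
            ((0, 1, 0), 65535),
            ((1, 0, 0), 16777215),
            ((255, 255, 255), (256**3 - 1) * 255 + (256**2 - 1) * 255 + 255 * 255),
        ],
    )
    def test_coefficients(self, rgb, key):
        assert rgb_to_value(*rgb) == key

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            rgb_to_value(256, 0, 0)
        with pytest.raises(ValueError):
            rgb_to_value(0, -1, 0)

    @given(
        a=st.tuples(*[st.integers(0, 255)] * 3),
        b=st.tuples(*[st.integers(0, 255)] * 3),
    )
    @settings(max_examples=300, derandomize=True)
    def test_injective(self, a, b):
        if a != b:
            assert rgb_to_value(*a) != rgb_to_value(*b)

    def test_injective_structural(self):
        # B term stays below the G coefficient, G+B terms below the R coefficient
        assert 255 * 255 < 256**2 - 1
        assert (256**2 - 1) * 255 + 255 * 255 < 256**3 - 1

    def test_injective_bulk_random_pairs(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 256, (100_000, 3))
        b = rng.integers(0, 256, (100_000, 3))
        differ = np.any(a != b, axis=1)
        ka = rgb_to_value(a[:, 0], a[:, 1], a[:, 2])
        kb = rgb_to_value(b[:, 0], b[:, 1], b[:, 2])
        assert np.all(ka[differ] != kb[differ])


class TestAttribution:
    def test_identity_lookup(self, scale):
        assert attribute_color(scale.colors[0], scale) == 0
        assert attribute_color(scale.colors[238], scale) == 238

    def test_absent_color_zero_tolerance_is_nodata(self, scale):
        # (1,2,3) is not a gray ramp entry
        assert attribute_color((1, 2, 3), scale, tolerance=0) == -1

    def test_nearest_within_tolerance(self, scale):
        c = scale.colors[100].astype(int)
        off = np.clip(c + np.array([0, 0, 1]), 0, 255)  # key distance 255
        assert attribute_color(tuple(off), scale, tolerance=255) == 100
        assert attribute_color(tuple(off), scale, tolerance=254) == -1

    def test_scrambled_palette_lookup_is_order_independent(self):
        scr = make_color_scale(50, mode="scrambled", seed=5)
        for i in (0, 17, 49):
            assert attribute_color(scr.colors[i], scr) == i

    def test_duplicate_colors_rejected(self):
        colors = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]], dtype=np.uint8)
        with pytest.raises(ValueError, match="distinct"):
            ColorScale(colors=colors)

    def test_embedded_strip_extraction(self, scale):
        img = np.zeros((10, 250, 3), dtype=np.uint8)
        img[3, 5 : 5 + 239] = scale.colors  # strip along row 3
        got = ColorScale.from_embedded(img, row=3, start=5, stop=5 + 239)
        assert np.array_equal(got.colors, scale.colors)
        with pytest.raises(ValueError, match="exactly one"):
            ColorScale.from_embedded(img)


class TestLevelMap:
    @pytest.mark.parametrize(
        "idx,tmin,tmax,expected",
        [(0, 10, 20, 10.0), (238, 10, 20, 20.0), (119, 0, 238, 119.0)],
    )
    def test_endpoints_and_midpoint(self, idx, tmin, tmax, expected):
        assert level_to_temperature(idx, tmin, tmax) == pytest.approx(expected, abs=1e-12)

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            level_to_temperature(239, 10, 20)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            level_to_temperature(0, 20, 10)

    def test_round_half_away_from_zero(self):
        # exactly between levels 0 and 1 -> level 1
        span = 238.0
        assert temperature_to_level(0.5, 0.0, span) == 1


class TestDecode:
    def test_uniform_image(self, scale):
        pix = np.broadcast_to(scale.colors[0], (4, 5, 3)).copy()
        s = ThermalSnapshot(pixels=pix, t_min=5, t_max=15, scale=scale)
        assert np.all(decode_snapshot(s) == 5.0)

    def test_full_palette_gives_239_distinct_temperatures(self, scale):
        pix = scale.colors.reshape(1, 239, 3)
        s = ThermalSnapshot(pixels=pix, t_min=10, t_max=40, scale=scale)
        t = decode_snapshot(s)
        assert len(np.unique(t)) == 239
        assert t.min() == 10.0 and t.max() == 40.0

    def test_roundtrip_within_half_step(self, scale):
        rng = np.random.default_rng(1)
        for _ in range(5):
            tmin, span = rng.uniform(-5, 20), rng.uniform(5, 40)
            grid = rng.uniform(tmin, tmin + span, (30, 40))
            s = encode_snapshot(grid, tmin, tmin + span, scale)
            err = np.abs(decode_snapshot(s) - grid)
            assert err.max() <= HALF_STEP(span) + 1e-12

    def test_unattributable_pixel_is_nan(self, scale):
        pix = np.broadcast_to(scale.colors[0], (2, 2, 3)).copy()
        pix[0, 0] = (1, 2, 3)
        s = ThermalSnapshot(pixels=pix, t_min=0, t_max=10, scale=scale)
        t = decode_snapshot(s)
        assert np.isnan(t[0, 0]) and np.isfinite(t[1, 1])


class TestCommonRange:
    def test_min_max(self):
        assert flight_common_range([(10, 20), (15, 30), (5, 12)]) == (5, 30)

    def test_singleton(self):
        assert flight_common_range([(10, 20)]) == (10, 20)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            flight_common_range([])

    def test_tight_against_direct_scan(self):
        rng = np.random.default_rng(2)
        lo = rng.uniform(0, 10, 20)
        ranges = [(l, l + s) for l, s in zip(lo, rng.uniform(1, 20, 20))]
        got = flight_common_range(ranges)
        assert got == (min(r[0] for r in ranges), max(r[1] for r in ranges))


class TestRescale:
    def test_identity_when_range_equals_common(self, scale):
        rng = np.random.default_rng(3)
        grid = rng.uniform(10, 30, (20, 20))
        s = encode_snapshot(grid, 10, 30, scale)
        out = rescale_snapshot(s, (10, 30), scale)
        assert np.array_equal(out.pixels, s.pixels)

    def test_uniform_snapshot_maps_to_expected_level(self, scale):
        # T=10 on common range (5, 20): level round(5/15*238) = 79
        pix = np.broadcast_to(scale.colors[0], (3, 3, 3)).copy()
        s = ThermalSnapshot(pixels=pix, t_min=10, t_max=11, scale=scale)
        out = rescale_snapshot(s, (5.0, 20.0), scale)
        assert np.all(out.pixels == scale.colors[79])

    def test_roundtrip_error_bounded_all_levels(self, scale):
        # every source level survives rescaling within half a common-range step
        pix = scale.colors.reshape(1, 239, 3)
        s = ThermalSnapshot(pixels=pix, t_min=12, t_max=28, scale=scale)
        common = (5.0, 35.0)
        before = decode_snapshot(s)
        after = decode_snapshot(rescale_snapshot(s, common, scale))
        assert np.abs(after - before).max() <= HALF_STEP(common[1] - common[0]) + 1e-12

    def test_non_enclosing_range_rejected(self, scale):
        pix = np.broadcast_to(scale.colors[0], (2, 2, 3)).copy()
        s = ThermalSnapshot(pixels=pix, t_min=0, t_max=50, scale=scale)
        with pytest.raises(ValueError):
            rescale_snapshot(s, (5.0, 20.0), scale)
        out = rescale_snapshot(s, (5.0, 20.0), scale, clamp=True)
        assert out.t_min == 5.0 and out.t_max == 20.0


class TestMosaicConversion:
    def _mosaic(self, scale, off_palette=0):
        rng = np.random.default_rng(4)
        levels = rng.integers(0, 239, (12, 15))
        rgb = scale.colors[levels]
        for k in range(off_palette):
            rgb[0, k] = (1, 2, 3)
        bands = np.moveaxis(rgb, -1, 0)
        r = Raster(bands, Affine.from_origin(0, 12 * 0.08, 0.08, 0.08), crs="LOCAL")
        return r, levels

    def test_exact_palette_zero_nodata(self, scale):
        mosaic, levels = self._mosaic(scale)
        out = mosaic_to_temperature_raster(mosaic, (5.0, 35.0), scale, tolerance=0)
        assert not np.isnan(out.values).any()
        expected = level_to_temperature(levels, 5.0, 35.0)
        assert np.allclose(out.values, expected)
        assert out.transform.as_tuple() == mosaic.transform.as_tuple()

    def test_single_off_palette_pixel(self, scale):
        mosaic, _ = self._mosaic(scale, off_palette=1)
        out = mosaic_to_temperature_raster(mosaic, (5.0, 35.0), scale, tolerance=0)
        assert np.isnan(out.values).sum() == 1

    def test_blended_color_snaps_to_nearest_entry(self, scale):
        rgb = np.clip(scale.colors[50].astype(int) + 1, 0, 255)  # near level 50
        bands = np.broadcast_to(np.array(rgb, np.uint8), (2, 2, 3))
        mosaic = Raster(np.moveaxis(bands, -1, 0).copy(), Affine.from_origin(0, 1, 0.5, 0.5))
        out = mosaic_to_temperature_raster(mosaic, (0.0, 238.0), scale)
        # brute-force nearest key
        keys = scale.keys
        k = int(rgb[0]) * (256**3 - 1) + int(rgb[1]) * (256**2 - 1) + int(rgb[2]) * 255
        nearest = int(np.argmin(np.abs(keys - k)))
        assert np.all(out.values == float(nearest))

    def test_ungeoreferenced_rejected(self, scale):
        bands = np.moveaxis(np.broadcast_to(scale.colors[0], (2, 2, 3)), -1, 0).copy()
        with pytest.raises(ValueError, match="georeferenced"):
            mosaic_to_temperature_raster(Raster(bands), (0.0, 10.0), scale)


class TestPPM:
    def test_p6_roundtrip_identical(self, tmp_path):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, (3, 4, 3)).astype(np.uint8)
        p = tmp_path / "a.ppm"
        write_ppm(img, p)
        assert np.array_equal(read_ppm(p), img)
        # byte-identical on rewrite
        write_ppm(read_ppm(p), tmp_path / "b.ppm")
        assert (tmp_path / "a.ppm").read_bytes() == (tmp_path / "b.ppm").read_bytes()

    def test_p3_decodes_like_p6(self, tmp_path):
        img = np.array([[[1, 2, 3], [200, 0, 255]]], dtype=np.uint8)
        p6, p3 = tmp_path / "x.ppm", tmp_path / "y.ppm"
        write_ppm(img, p6)
        flat = " ".join(str(v) for v in img.ravel())
        p3.write_text(f"P3\n# comment\n2 1\n255\n{flat}\n")
        assert np.array_equal(read_ppm(p3), read_ppm(p6))

    @pytest.mark.parametrize(
        "content",
        [
            b"P6\n2 1\n65535\n" + b"\x00" * 12,  # wrong maxval
            b"P6\n2 1\n255\n\x00\x00",  # truncated payload
            b"P5\n2 1\n255\n\x00\x00",  # not a pixmap
            b"P6\nnot numbers\n",  # malformed header
        ],
    )
    def test_malformed_rejected(self, tmp_path, content):
        p = tmp_path / "bad.ppm"
        p.write_bytes(content)
        with pytest.raises(ValueError):
            read_ppm(p)
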