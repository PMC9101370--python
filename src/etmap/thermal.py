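"""Pseudo-color thermal snapshot codec.

Compact thermal cameras in snapshot mode save pseudo-colored frames in
which each color encodes a temperature relative to a *per-frame*
min/max range, via an ordered colorbar of 239 distinct colors: the
darkest entry maps to the frame minimum, the brightest to the frame
maximum, with the range divided linearly over the 239 levels. Because
every frame autoscales its own range, frames must be decoded to
physical temperature and re-encoded against a single flight-wide range
before mosaicking.

Colors are compared through a 24-bit scalar key,

    key(R, G, B) = (256**3 - 1)*R + (256**2 - 1)*G + 255*B,

which is injective over 8-bit triples (the B term is at most
255*255 = 65025, strictly below the G coefficient 65535, and the G+B
terms together stay strictly below the R coefficient 16777215), so the
color-to-level attribution is unambiguous.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from etmap.raster import Raster

N_LEVELS_DEFAULT = 239

_KR = 256**3 - 1
_KG = 256**2 - 1
_KB = 255


def rgb_to_value(r, g, b):
    """24-bit-range scalar key of an 8-bit color triple.

    ``key = (256**3 - 1)*R + (256**2 - 1)*G + 255*B``; injective over
    all 8-bit triples, so two distinct colors never share a key.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=np.int64)
    g = np.asarray(g, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if np.any((r < 0) | (r > 255) | (g < 0) | (g > 255) | (b < 0) | (b > 255)):
        raise ValueError("channel values must be 8-bit (0..255)")
    key = _KR * r + _KG * g + _KB * b
    return int(key) if key.ndim == 0 else key


@dataclass(frozen=True)
class ColorScale:
    """An ordered colorbar: level index -> 8-bit (R, G, B) color.

    Index 0 is the darkest entry (lowest key), index ``n_levels - 1``
    the brightest (highest key). All colors must be distinct.
    """

    colors: np.ndarray  # (n_levels, 3) uint8

    def __post_init__(self) -> None:
        colors = np.asarray(self.colors, dtype=np.uint8)
        if colors.ndim != 2 or colors.shape[1] != 3 or colors.shape[0] < 2:
            raise ValueError("ColorScale needs an (n>=2, 3) array of colors")
        keys = rgb_to_value(colors[:, 0], colors[:, 1], colors[:, 2])
        if len(np.unique(keys)) != len(keys):
            raise ValueError("ColorScale colors must be distinct under the 24-bit key")
        object.__setattr__(self, "colors", colors)
        object.__setattr__(self, "_keys", keys)
        order = np.argsort(keys, kind="stable")
        object.__setattr__(self, "_sorted_keys", keys[order])
        object.__setattr__(self, "_sorted_levels", order)

    @property
    def n_levels(self) -> int:
        return self.colors.shape[0]

    @property
    def keys(self) -> np.ndarray:
        return self._keys

    @classmethod
    def from_strip(cls, path: str | Path) -> "ColorScale":
        """Load a colorbar from an N×1 (or 1×N) PPM strip image."""
        img = read_ppm(path)
        if img.shape[0] == 1:
            img = img.transpose(1, 0, 2)
        if img.shape[1] != 1:
            raise ValueError("colorbar strip must be a single row or column image")
        return cls(colors=img[:, 0, :])

    def to_strip(self, path: str | Path) -> None:
        write_ppm(self.colors[:, None, :], path)

    @classmethod
    def from_embedded(
        cls,
        image: np.ndarray,
        row: int | None = None,
        col: int | None = None,
        start: int = 0,
        stop: int | None = None,
    ) -> "ColorScale":
        """Extract a colorbar embedded in a snapshot image.

        Reads the strip along row ``row`` (or column ``col``) between
        pixel positions ``start`` and ``stop``. Exactly one of row/col
        must be given.
        """
        image = np.asarray(image)
        if (row is None) == (col is None):
            raise ValueError("give exactly one of row= or col=")
        strip = image[row, start:stop, :] if row is not None else image[start:stop, col, :]
        return cls(colors=strip)


@dataclass(frozen=True)
class ThermalSnapshot:
    """A pseudo-colored frame with its per-frame temperature range."""

    pixels: np.ndarray  # (H, W, 3) uint8
    t_min: float  # °C
    t_max: float  # °C
    scale: ColorScale
    snapshot_id: int = 0
    timestamp: float = 0.0  # seconds

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=np.uint8)
        if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.shape[0] < 1 or pixels.shape[1] < 1:
            raise ValueError("pixels must be an (H, W, 3) 8-bit array")
        if not self.t_max > self.t_min:
            raise ValueError("t_max must exceed t_min")
        object.__setattr__(self, "pixels", pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def attribute_color(color, scale: ColorScale, tolerance: int = 0):
    """Level index of a color in the scale, by 24-bit key lookup.

    Exact matches return their level directly. Otherwise the nearest
    key within ``tolerance`` key units wins (ties -> lower key); beyond
    tolerance the result is -1 (nodata). Accepts one (R, G, B) triple
    or an (..., 3) array; returns int or int array.
    """
    color = np.asarray(color, dtype=np.uint8)
    single = color.ndim == 1
    color = np.atleast_2d(color)
    flat = color.reshape(-1, 3)
    keys = rgb_to_value(flat[:, 0], flat[:, 1], flat[:, 2])
    keys = np.atleast_1d(keys)
    sk, sl = scale._sorted_keys, scale._sorted_levels
    pos = np.searchsorted(sk, keys)
    lo = np.clip(pos - 1, 0, len(sk) - 1)
    hi = np.clip(pos, 0, len(sk) - 1)
    d_lo = np.abs(keys - sk[lo])
    d_hi = np.abs(keys - sk[hi])
    pick_lo = d_lo <= d_hi  # tie -> lower key
    nearest = np.where(pick_lo, lo, hi)
    dist = np.where(pick_lo, d_lo, d_hi)
    levels = np.where(dist <= tolerance, sl[nearest], -1)
    if single:
        return int(levels[0])
    return levels.reshape(color.shape[:-1])


def level_to_temperature(index, t_min: float, t_max: float, n_levels: int = N_LEVELS_DEFAULT):
    """Temperature of a level: linear map with inclusive endpoints.

    ``T = t_min + index * (t_max - t_min) / (n_levels - 1)``, so level 0
    is exactly ``t_min`` and level ``n_levels - 1`` exactly ``t_max``.
    """
    if not t_max > t_min:
        raise ValueError("t_max must exceed t_min")
    idx = np.asarray(index)
    if np.any((idx < 0) | (idx > n_levels - 1)):
        raise ValueError(f"level index out of range 0..{n_levels - 1}")
    t = t_min + idx * (t_max - t_min) / (n_levels - 1)
    return float(t) if np.ndim(index) == 0 else t


def decode_snapshot(s: ThermalSnapshot, tolerance: int = 0) -> np.ndarray:
    """Per-pixel temperature grid (°C); unattributable pixels -> NaN."""
    levels = attribute_color(s.pixels, s.scale, tolerance=tolerance)
    t = np.full(s.shape, np.nan)
    ok = levels >= 0
    t[ok] = level_to_temperature(levels[ok], s.t_min, s.t_max, s.scale.n_levels)
    return t


def flight_common_range(ranges) -> tuple[float, float]:
    """Flight-wide (min of mins, max of maxes) over per-snapshot ranges."""
    ranges = list(ranges)
    if not ranges:
        raise ValueError("need at least one snapshot range")
    lo = min(r[0] for r in ranges)
    hi = max(r[1] for r in ranges)
    return (lo, hi)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (symmetric quantization)."""
    return np.trunc(x + np.copysign(0.5, x))


def temperature_to_level(
    t, t_min: float, t_max: float, n_levels: int = N_LEVELS_DEFAULT, clamp: bool = False
):
    """Nearest level of a temperature in a range (inverse of the level map)."""
    t = np.asarray(t, dtype=float)
    if clamp:
        t = np.clip(t, t_min, t_max)
    elif np.any((t < t_min) | (t > t_max)):
        raise ValueError("temperature outside the encoding range")
    lev = _round_half_away((t - t_min) / (t_max - t_min) * (n_levels - 1)).astype(int)
    return np.clip(lev, 0, n_levels - 1)


def rescale_snapshot(
    s: ThermalSnapshot,
    common: tuple[float, float],
    scale: ColorScale | None = None,
    clamp: bool = False,
) -> ThermalSnapshot:
    """Re-encode a snapshot against a flight-wide common range.

    Each pixel is decoded to temperature using the snapshot's own range
    and assigned the scale entry nearest to it on the common range, so
    all rescaled snapshots of a flight share one colorbar-to-temperature
    mapping and can be mosaicked. Decoding the result reproduces the
    temperature within half a common-range quantization step.
    """
    lo, hi = common
    if not hi > lo:
        raise ValueError("common range must have max > min")
    if not clamp and (s.t_min < lo - 1e-12 or s.t_max > hi + 1e-12):
        raise ValueError("common range does not enclose the snapshot range (use clamp=True)")
    scale = scale or s.scale
    t = decode_snapshot(s)
    levels = temperature_to_level(np.nan_to_num(t, nan=lo), lo, hi, scale.n_levels, clamp=clamp)
    pixels = scale.colors[levels]
    pixels[np.isnan(t)] = scale.colors[0]
    return replace(s, pixels=pixels, t_min=lo, t_max=hi, scale=scale)


def mosaic_to_temperature_raster(
    mosaic: Raster,
    common: tuple[float, float],
    scale: ColorScale,
    tolerance: int = 3 * 255,
) -> Raster:
    """Convert a 3-band pseudo-color mosaic to a 1-band temperature raster.

    Mosaicking blends colors at seam lines, so attribution uses a
    nearest-key search within ``tolerance`` (default 3·255 key units);
    pixels beyond tolerance become NaN nodata. Georeferencing is
    preserved.
    """
    lo, hi = common
    if not hi > lo:
        raise ValueError("common range must have max > min")
    if mosaic.count != 3:
        raise ValueError("thermal mosaic must have exactly 3 bands")
    from etmap.raster import Affine

    if mosaic.transform.as_tuple() == Affine.identity().as_tuple():
        raise ValueError("mosaic is not georeferenced")
    rgb = np.stack([mosaic.band(0), mosaic.band(1), mosaic.band(2)], axis=-1).astype(np.uint8)
    levels = attribute_color(rgb, scale, tolerance=tolerance)
    t = np.full(levels.shape, np.nan, dtype=np.float32)
    ok = levels >= 0
    t[ok] = level_to_temperature(levels[ok], lo, hi, scale.n_levels)
    return Raster(values=t, transform=mosaic.transform, crs=mosaic.crs, nodata=None)


# -- Portable Pixmap input/output ------------------------------------------


def _read_token(buf: io.BufferedReader) -> bytes:
    """Next whitespace-delimited token, skipping '#' comments."""
    tok = b""
    while True:
        ch = buf.read(1)
        if ch == b"":
            if tok:
                return tok
            raise ValueError("truncated PPM header")
        if ch == b"#":
            while ch not in (b"\n", b""):
                ch = buf.read(1)
            continue
        if ch.isspace():
            if tok:
                return tok
            continue
        tok += ch


def read_ppm(path: str | Path) -> np.ndarray:
    """Read a PPM image as an (H, W, 3) uint8 array.

    Binary P6 is the native dialect; ASCII P3 is accepted and decoded
    identically. Maxval must be 255.
    """
    with open(path, "rb") as f:
        buf = io.BufferedReader(f)
        magic = _read_token(buf)
        if magic not in (b"P6", b"P3"):
            raise ValueError(f"{path}: not a PPM file (magic {magic!r})")
        try:
            width = int(_read_token(buf))
            height = int(_read_token(buf))
            maxval = int(_read_token(buf))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed PPM header") from exc
        if width <= 0 or height <= 0:
            raise ValueError(f"{path}: non-positive PPM dimensions")
        if maxval != 255:
            raise ValueError(f"{path}: unsupported maxval {maxval} (must be 255)")
        n = width * height * 3
        if magic == b"P6":
            payload = buf.read(n)
            if len(payload) != n:
                raise ValueError(f"{path}: truncated PPM payload")
            data = np.frombuffer(payload, dtype=np.uint8)
        else:
            rest = buf.read().split()
            if len(rest) < n:
                raise ValueError(f"{path}: truncated PPM payload")
            data = np.array([int(v) for v in rest[:n]], dtype=np.uint8)
    return data.reshape(height, width, 3)


def write_ppm(image: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) uint8 array as binary P6 with maxval 255."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("PPM image must be (H, W, 3)")
    image = image.astype(np.uint8)
    h, w = image.shape[:2]
    with open(path, "wb") as f:
        f.write(f"P6\n{w} {h}\n255\n".encode("ascii"))
        f.write(image.tobytes())
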