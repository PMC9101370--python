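"""Georeferenced raster container and GeoTIFF input/output.

The container is deliberately small: a numpy array, an affine
grid-to-world transform, a CRS identifier string and an optional nodata
value. GeoTIFF files are read and written through :mod:`tifffile` using
the ModelPixelScale / ModelTiepoint GeoTIFF tags (axis-aligned,
north-up transforms) and the GDAL nodata tag.

Conventions follow the GDAL model: the affine transform maps the
*corner* of pixel (row=0, col=0) to world coordinates; pixel centers sit
at half-pixel offsets. Single-band rasters are 2-D ``(rows, cols)``
arrays; multiband rasters are 3-D ``(bands, rows, cols)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

# GeoTIFF / GDAL private tags
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class Affine:
    """Planar affine transform ``(col, row) -> (x, y)``.

    ``x = c + a*col + b*row`` and ``y = f + d*col + e*row`` — the same
    six-parameter layout used by GDAL and rasterio (``e`` is negative
    for north-up rasters).
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def identity(cls) -> "Affine":
        return cls(1.0, 0.0, 0.0, 0.0, 1.0, 0.0)

    @classmethod
    def from_origin(cls, west: float, north: float, xsize: float, ysize: float) -> "Affine":
        """North-up transform from the upper-left corner and pixel sizes."""
        return cls(xsize, 0.0, west, 0.0, -ysize, north)

    def __call__(self, col, row):
        return (self.c + self.a * col + self.b * row, self.f + self.d * col + self.e * row)

    def invert(self) -> "Affine":
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("affine transform is singular")
        ia, ib = self.e / det, -self.b / det
        id_, ie = -self.d / det, self.a / det
        ic = -(ia * self.c + ib * self.f)
        if_ = -(id_ * self.c + ie * self.f)
        return Affine(ia, ib, ic, id_, ie, if_)

    def world_to_pixel(self, x, y):
        """Inverse map ``(x, y) -> (col, row)`` (fractional)."""
        inv = self.invert()
        return inv(x, y)

    @property
    def is_rectilinear(self) -> bool:
        return self.b == 0.0 and self.d == 0.0

    def as_tuple(self):
        return (self.a, self.b, self.c, self.d, self.e, self.f)


@dataclass
class Raster:
    """An in-memory georeferenced raster."""

    values: np.ndarray
    transform: Affine = field(default_factory=Affine.identity)
    crs: str = "LOCAL"
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ValueError("raster values must be 2-D (band) or 3-D (bands, rows, cols)")

    @property
    def count(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[-2:]

    @property
    def resolution(self) -> tuple[float, float]:
        t = self.transform
        return (float(np.hypot(t.a, t.d)), float(np.hypot(t.b, t.e)))

    def band(self, i: int) -> np.ndarray:
        return self.values if self.values.ndim == 2 else self.values[i]

    def xy(self, row, col):
        """World coordinates of pixel *centers*."""
        return self.transform(np.asarray(col) + 0.5, np.asarray(row) + 0.5)

    def index(self, x, y):
        """Integer (row, col) of the pixel containing world point (x, y)."""
        col, row = self.transform.world_to_pixel(x, y)
        return np.floor(row).astype(int), np.floor(col).astype(int)

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) world coordinates of every pixel center, as 2-D arrays."""
        h, w = self.shape
        rows, cols = np.mgrid[0:h, 0:w]
        x, y = self.xy(rows, cols)
        return np.asarray(x), np.asarray(y)

    def valid_mask(self) -> np.ndarray:
        band = self.values if self.values.ndim == 2 else self.values[0]
        mask = np.isfinite(band) if band.dtype.kind == "f" else np.ones(band.shape, bool)
        if self.nodata is not None:
            mask &= band != self.nodata
        return mask

    def same_grid(self, other: "Raster", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and np.allclose(self.transform.as_tuple(), other.transform.as_tuple(), atol=atol)
        )

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "Raster":
        return replace(self, values=np.asarray(values), nodata=nodata)


def _crs_geokeys(crs: str):
    """Minimal GeoKeyDirectory (+ optional ASCII params) for a CRS string."""
    keys = []
    ascii_params = None
    if crs.upper().startswith("EPSG:"):
        code = int(crs.split(":")[1])
        if 4000 <= code < 5000:  # geographic
            keys = [(1024, 0, 1, 2), (2048, 0, 1, code)]
        else:
            keys = [(1024, 0, 1, 1), (3072, 0, 1, code)]
    else:
        ascii_params = crs + "|"
        keys = [(1024, 0, 1, 32767), (1026, _TAG_GEO_ASCII_PARAMS, len(ascii_params), 0)]
    header = [1, 1, 0, len(keys)]
    flat = header + [v for k in keys for v in k]
    return flat, ascii_params


def _geokeys_to_crs(directory, ascii_params: str | None) -> str:
    vals = list(directory)
    n = vals[3]
    entries = {}
    for i in range(n):
        kid, loc, cnt, off = vals[4 + 4 * i : 8 + 4 * i]
        entries[kid] = (loc, cnt, off)
    if 2048 in entries and entries[2048][0] == 0:
        return f"EPSG:{entries[2048][2]}"
    if 3072 in entries and entries[3072][0] == 0:
        return f"EPSG:{entries[3072][2]}"
    if 1026 in entries and ascii_params:
        loc, cnt, off = entries[1026]
        return ascii_params[off : off + cnt].rstrip("|")
    return "LOCAL"


def write_geotiff(raster: Raster, path: str | Path) -> None:
    """Write a Raster as a GeoTIFF (axis-aligned transforms only).

    Single-band rasters become one sample per pixel; 3-band byte rasters
    are written as RGB. The nodata value goes into the GDAL nodata tag.
    """
    t = raster.transform
    if not t.is_rectilinear:
        raise ValueError("GeoTIFF output requires an axis-aligned (rectilinear) transform")
    scale = (abs(t.a), abs(t.e), 0.0)
    tiepoint = (0.0, 0.0, 0.0, t.c, t.f, 0.0)
    keys, ascii_params = _crs_geokeys(raster.crs)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, scale),
        (_TAG_MODEL_TIEPOINT, "d", 6, tiepoint),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(keys), tuple(keys)),
    ]
    if ascii_params is not None:
        extratags.append((_TAG_GEO_ASCII_PARAMS, "s", len(ascii_params), ascii_params))
    if raster.nodata is not None:
        nd = str(raster.nodata)
        extratags.append((_TAG_GDAL_NODATA, "s", len(nd), nd))
    data = raster.values
    kwargs = {"photometric": "minisblack"}
    if data.ndim == 3:
        if data.shape[0] == 3 and data.dtype == np.uint8:
            data = np.moveaxis(data, 0, -1)  # interleaved RGB
            kwargs = {"photometric": "rgb"}
        else:
            kwargs["planarconfig"] = "separate"  # one image, N samples/pixel
    tifffile.imwrite(str(path), data, extratags=extratags, **kwargs)


def read_geotiff(path: str | Path) -> Raster:
    """Read a GeoTIFF written by :func:`write_geotiff` or GDAL (north-up)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeferencing (ModelPixelScale/ModelTiepoint)")
        sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value
        i, j, _, x, y, _ = tags[_TAG_MODEL_TIEPOINT].value[:6]
        west = x - i * sx
        north = y + j * sy
        transform = Affine.from_origin(west, north, sx, sy)
        crs = "LOCAL"
        if _TAG_GEO_KEY_DIRECTORY in tags:
            ascii_params = (
                tags[_TAG_GEO_ASCII_PARAMS].value if _TAG_GEO_ASCII_PARAMS in tags else None
            )
            crs = _geokeys_to_crs(tags[_TAG_GEO_KEY_DIRECTORY].value, ascii_params)
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        planar = getattr(page, "planarconfig", 1) == 2
    if data.ndim == 3 and not planar:
        data = np.moveaxis(data, -1, 0)  # interleaved -> (bands, rows, cols)
    return Raster(values=data, transform=transform, crs=crs, nodata=nodata)


# -- local metric projection ------------------------------------------------

#: Sphere radius used for all geodesic work, m (GRS80/WGS-84 semi-major axis).
EARTH_RADIUS = 6_378_137.0


class LocalTangentPlane:
    """Equirectangular projection about a reference lat/lon.

    Adequate for UAV-scale scenes (sub-millimeter distortion over a few
    hundred meters); x points east, y points north, units meters.
    """

    def __init__(self, lat0: float, lon0: float):
        self.lat0 = float(lat0)
        self.lon0 = float(lon0)
        self._coslat = np.cos(np.radians(lat0))

    def forward(self, lat, lon):
        x = np.radians(np.asarray(lon) - self.lon0) * EARTH_RADIUS * self._coslat
        y = np.radians(np.asarray(lat) - self.lat0) * EARTH_RADIUS
        return x, y

    def inverse(self, x, y):
        lon = self.lon0 + np.degrees(np.asarray(x) / (EARTH_RADIUS * self._coslat))
        lat = self.lat0 + np.degrees(np.asarray(y) / EARTH_RADIUS)
        return lat, lon


def haversine(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS):
    """Great-circle distance in meters on a sphere (default R=6 378 137 m)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
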