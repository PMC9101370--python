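"""Surface-parameter rasters for the energy-balance model.

Builds the non-thermal inputs on the thermal grid (~8 cm): a visible
vegetation index from the RGB orthomosaic, a leaf-area-index (LAI) map
from an index-vs-ceptometer regression, and the fractional cover /
green fraction pair. Two visible-band indices are supported:

* VI   = (G − R) / (G + R)          (green–red ratio index)
* VARI = (G − R) / (G + R − B)      (visible atmospherically resistant index)

Site modes encode the two canopy assumptions: on grassland the cover is
total (f_c ≡ 1) and the *green fraction* is estimated from the RGB green
signal; on cropland all vegetation is green (f_g ≡ 1) and the
*fractional cover* is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from etmap.raster import Raster

INDEX_KINDS = ("VI", "VARI")


@dataclass(frozen=True)
class LAIModel:
    """Linear LAI model ``LAI = slope * index + intercept``."""

    index_kind: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def _normalized_bands(rgb: Raster) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if rgb.count != 3:
        raise ValueError("RGB raster must have exactly 3 bands")
    bands = [np.asarray(rgb.band(i), dtype=float) for i in range(3)]
    if rgb.values.dtype == np.uint8:
        bands = [b / 255.0 for b in bands]
    return bands[0], bands[1], bands[2]


def compute_index(rgb: Raster, kind: str = "VARI") -> Raster:
    """Visible vegetation index raster; zero-denominator pixels -> NaN."""
    if kind not in INDEX_KINDS:
        raise ValueError(f"unknown index kind {kind!r}")
    r, g, b = _normalized_bands(rgb)
    denom = (g + r - b) if kind == "VARI" else (g + r)
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(denom != 0, (g - r) / denom, np.nan)
    return Raster(values=idx, transform=rgb.transform, crs=rgb.crs, nodata=None)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares y = slope*x + intercept; returns (slope, b, R²)."""
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: index values are constant")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def fit_lai_model(points) -> LAIModel:
    """Fit LAI against both indices; keep whichever gives the higher R².

    ``points`` is a sequence of (lai, vi, vari) triples from ceptometer
    ground measurements and index values sampled at the same locations.
    Ties in R² go to VARI.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (lai, vi, vari) points")
    lai = pts[:, 0]
    fits = {}
    for kind, col in (("VI", 1), ("VARI", 2)):
        try:
            fits[kind] = _ols(pts[:, col], lai)
        except ValueError:
            pass
    if not fits:
        raise ValueError("degenerate fit: both index columns are constant")
    best = max(fits, key=lambda k: (fits[k][2], k == "VARI"))
    slope, intercept, r2 = fits[best]
    return LAIModel(index_kind=best, slope=slope, intercept=intercept,
                    r_squared=r2, n_points=pts.shape[0])


def lai_map(model: LAIModel, index: Raster, index_kind: str | None = None) -> Raster:
    """Apply a fitted LAI model to an index raster; clamp below at 0."""
    if index_kind is not None and index_kind != model.index_kind:
        raise ValueError(
            f"index raster is {index_kind}, model was fitted on {model.index_kind}"
        )
    vals = np.asarray(index.band(0), dtype=float)
    lai = model.slope * vals + model.intercept
    lai = np.where(np.isnan(vals), np.nan, np.maximum(lai, 0.0))
    return Raster(values=lai, transform=index.transform, crs=index.crs, nodata=None)


def _bimodal_split(values: np.ndarray, bins: int = 256) -> float:
    """Otsu threshold (maximal between-class variance) on a 1-D sample."""
    values = values[np.isfinite(values)]
    hist, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_all = cum_m[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mean_all * cum_w - cum_m) ** 2 / (cum_w * (total - cum_w))
    between[~np.isfinite(between)] = -1.0
    return float(centers[int(np.argmax(between))])


def green_mask(rgb: Raster, threshold: float | None = 0.05) -> Raster:
    """Binary green-vegetation mask: VARI > threshold.

    ``threshold=None`` picks the threshold automatically by a bimodal
    histogram split (Otsu) of the VARI values.
    """
    vari = compute_index(rgb, "VARI").band(0)
    if threshold is None:
        threshold = _bimodal_split(vari)
    mask = np.where(np.isnan(vari), False, vari > threshold)
    return Raster(values=mask.astype(np.uint8), transform=rgb.transform, crs=rgb.crs)


def _target_cell_of_centers(src: Raster, target: Raster) -> tuple[np.ndarray, np.ndarray]:
    """Flat target-cell index of every source pixel center (−1 = outside)."""
    x, y = src.center_grids()
    row, col = target.index(x, y)
    h, w = target.shape
    inside = (row >= 0) & (row < h) & (col >= 0) & (col < w)
    flat = np.where(inside, row * w + col, -1)
    return flat.ravel(), inside.ravel()


def fraction_raster(mask: Raster, target: Raster, site_mode: str | None = None):
    """Per-target-cell fraction of true sub-pixels of a finer binary mask.

    With ``site_mode`` given, returns the (f_c, f_g) raster pair:
    ``"grassland"`` fixes f_c ≡ 1 and puts the fraction in f_g;
    ``"cropland"`` fixes f_g ≡ 1 and puts the fraction in f_c.
    Without it, returns the bare fraction raster.
    """
    if mask.crs != target.crs:
        raise ValueError(f"CRS mismatch: mask {mask.crs!r} vs target {target.crs!r}")
    if mask.resolution[0] > target.resolution[0] * (1 + 1e-9):
        raise ValueError("mask resolution must be finer than or equal to the target grid")
    flat, inside = _target_cell_of_centers(mask, target)
    vals = np.asarray(mask.band(0), dtype=float).ravel()
    h, w = target.shape
    counts = np.bincount(flat[inside], minlength=h * w).astype(float)
    sums = np.bincount(flat[inside], weights=vals[inside], minlength=h * w)
    with np.errstate(invalid="ignore"):
        frac = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    frac = frac.reshape(h, w)
    out = Raster(values=frac, transform=target.transform, crs=target.crs)
    if site_mode is None:
        return out
    ones = out.with_values(np.where(np.isnan(frac), np.nan, 1.0))
    if site_mode == "grassland":
        return ones, out  # f_c ≡ 1, f_g estimated
    if site_mode == "cropland":
        return out, ones  # f_c estimated, f_g ≡ 1
    raise ValueError(f"unknown site mode {site_mode!r}")


def resample_to_grid(src: Raster, target: Raster, method: str = "mean") -> Raster:
    """Resample a raster onto another raster's grid.

    ``"mean"`` aggregates source pixel centers falling in each target
    cell (continuous fields); ``"nearest"`` samples the source at each
    target cell center (categorical fields). NaN-aware.
    """
    if src.crs != target.crs:
        raise ValueError(f"CRS mismatch: {src.crs!r} vs {target.crs!r}")
    sx0, sy0 = src.xy(0, 0)
    sx1, sy1 = src.xy(src.shape[0] - 1, src.shape[1] - 1)
    tx0, ty0 = target.xy(0, 0)
    tx1, ty1 = target.xy(target.shape[0] - 1, target.shape[1] - 1)
    if (max(min(sx0, sx1), min(tx0, tx1)) > min(max(sx0, sx1), max(tx0, tx1))) or (
        max(min(sy0, sy1), min(ty0, ty1)) > min(max(sy0, sy1), max(ty0, ty1))
    ):
        raise ValueError("source and target extents are disjoint")
    h, w = target.shape
    if method == "nearest":
        x, y = target.center_grids()
        col, row = src.transform.world_to_pixel(x, y)
        row = np.clip(np.round(row - 0.5).astype(int), 0, src.shape[0] - 1)
        col = np.clip(np.round(col - 0.5).astype(int), 0, src.shape[1] - 1)
        vals = np.asarray(src.band(0))[row, col]
        return Raster(values=vals, transform=target.transform, crs=target.crs, nodata=src.nodata)
    if method != "mean":
        raise ValueError(f"unknown resampling method {method!r}")
    flat, inside = _target_cell_of_centers(src, target)
    vals = np.asarray(src.band(0), dtype=float).ravel()
    valid = inside & np.isfinite(vals)
    if src.nodata is not None:
        valid &= vals != src.nodata
    counts = np.bincount(flat[valid], minlength=h * w).astype(float)
    sums = np.bincount(flat[valid], weights=vals[valid], minlength=h * w)
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan).reshape(h, w)
    return Raster(values=mean, transform=target.transform, crs=target.crs)


def sample_window(raster: Raster, x: float, y: float, size: int = 5) -> float:
    """Mean of a size×size pixel window centered on a world point.

    Used to extract index values at ceptometer/marker locations without
    single-pixel noise. NaN pixels are ignored.
    """
    row, col = raster.index(x, y)
    half = size // 2
    h, w = raster.shape
    r0, r1 = max(row - half, 0), min(row + half + 1, h)
    c0, c1 = max(col - half, 0), min(col + half + 1, w)
    window = np.asarray(raster.band(0), dtype=float)[r0:r1, c0:c1]
    return float(np.nanmean(window))


@dataclass
class SurfaceInputs:
    """Co-registered model inputs on the thermal grid."""

    t_rad: Raster  # radiometric surface temperature, °C
    lai: Raster  # leaf area index, m²/m²
    f_c: Raster  # fractional cover, 0..1
    f_g: Raster  # green fraction of the cover, 0..1

    def __post_init__(self) -> None:
        for name in ("lai", "f_c", "f_g"):
            r = getattr(self, name)
            if not self.t_rad.same_grid(r):
                raise ValueError(f"{name} raster is not co-registered with t_rad")
        for name, lo, hi in (("f_c", 0.0, 1.0), ("f_g", 0.0, 1.0)):
            v = getattr(self, name).band(0)
            v = v[np.isfinite(v)]
            if v.size and (v.min() < lo - 1e-9 or v.max() > hi + 1e-9):
                raise ValueError(f"{name} must lie in [0, 1]")
        lai = self.lai.band(0)
        if np.any(lai[np.isfinite(lai)] < 0):
            raise ValueError("lai must be non-negative")
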