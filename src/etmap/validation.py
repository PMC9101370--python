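"""Validation of modelled latent heat against eddy-covariance fluxes.

The eddy-covariance (EC) tower measures turbulent fluxes from an
upwind source area (the footprint). The footprint is represented
simply: a 10 m diameter disk centered at the footprint peak, which
lies ``peak_distance`` meters from the tower along the direction the
wind comes from (meteorological bearing, clockwise from north).
Modelled latent heat is averaged over the disk and compared to the EC
flux after closing the measured energy balance by residual — the
imbalance is attributed entirely to latent heat, mirroring how the
two-source model computes LE as the balance remainder:

    LE_closed = Rn - G - H_ec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from etmap.raster import Raster


@dataclass(frozen=True)
class FootprintSpec:
    """Footprint-peak disk in the raster's (metric) coordinate system."""

    tower_x: float
    tower_y: float
    wind_direction: float  # ° the wind comes FROM, clockwise from north
    peak_distance: float  # m
    disk_diameter: float = 10.0  # m

    def __post_init__(self) -> None:
        if not 0.0 <= self.wind_direction < 360.0:
            raise ValueError("wind_direction must be in [0, 360)")
        if self.peak_distance < 0:
            raise ValueError("peak_distance must be non-negative")
        if self.disk_diameter <= 0:
            raise ValueError("disk_diameter must be positive")

    @property
    def center(self) -> tuple[float, float]:
        """Disk center: displaced upwind from the tower along the bearing."""
        theta = np.radians(self.wind_direction)
        return (
            self.tower_x + self.peak_distance * np.sin(theta),
            self.tower_y + self.peak_distance * np.cos(theta),
        )


@dataclass(frozen=True)
class ECRecord:
    """One half-hour eddy-covariance record."""

    time: float
    h_ec: float  # W/m²
    le_ec: float  # W/m²
    rn: float  # W/m²
    g: float  # W/m²
    wind_direction: float = 0.0  # °
    peak_distance: float = 0.0  # m

    def __post_init__(self) -> None:
        for name in ("h_ec", "le_ec", "rn", "g"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def footprint_disk(spec: FootprintSpec, grid: Raster) -> Raster:
    """Binary mask of pixels whose centers fall inside the footprint disk."""
    cx, cy = spec.center
    x, y = grid.center_grids()
    r = spec.disk_diameter / 2.0
    mask = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
    if not mask.any():
        raise ValueError(
            f"footprint disk at ({cx:.1f}, {cy:.1f}) r={r:.1f} m does not intersect the raster"
        )
    return Raster(values=mask.astype(np.uint8), transform=grid.transform, crs=grid.crs)


def average_over_mask(band: np.ndarray, mask: Raster | np.ndarray) -> tuple[float, int]:
    """Arithmetic mean of valid (finite) pixels under a binary mask.

    Returns ``(mean, n_valid)``; raises if no valid pixel falls under
    the mask.
    """
    m = mask.band(0).astype(bool) if isinstance(mask, Raster) else np.asarray(mask, bool)
    vals = np.asarray(band, dtype=float)[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid pixels under the footprint mask")
    return float(vals.mean()), int(vals.size)


def close_ec_balance(rec: ECRecord, method: str = "residual_le") -> float:
    """Close the measured energy balance by residual, into latent heat.

    ``LE_closed = Rn - G - H_ec``: the entire imbalance is assigned to
    the latent heat flux. Other closure variants (H-side, Bowen-ratio)
    are recognized config names but not implemented.
    """
    if method != "residual_le":
        raise NotImplementedError(f"closure method {method!r} is not implemented")
    return rec.rn - rec.g - rec.h_ec


def match_ec_record(records, flight_midpoint: float, interval: float = 1800.0) -> ECRecord:
    """EC record whose averaging interval contains the flight midpoint.

    ``rec.time`` marks the *end* of the half-hour averaging interval.
    """
    for rec in records:
        if rec.time - interval <= flight_midpoint <= rec.time:
            return rec
    raise ValueError("no EC record covers the flight midpoint time")


@dataclass(frozen=True)
class ValidationStats:
    rmse: float
    rmsd: float  # scatter about the mean bias (bias-removed RMSE)
    bias: float  # mean (modelled - measured)
    slope: float
    intercept: float
    r: float  # Pearson correlation (NaN when degenerate)
    p: float  # two-sided p-value of r
    n: int


def validation_stats(pairs) -> ValidationStats:
    """Model-vs-measurement statistics for (modelled, measured) pairs.

    RMSE is the root-mean-square difference; RMSD the root-mean-square
    deviation about the mean difference, so RMSE² = bias² + RMSD².
    The regression is ordinary least squares of modelled on measured;
    r/p are Pearson. Degenerate inputs (either side constant) flag the
    correlation as NaN.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (modelled, measured) pairs")
    mod, mea = arr[:, 0], arr[:, 1]
    diff = mod - mea
    bias = float(diff.mean())
    rmse = float(np.sqrt(np.mean(diff**2)))
    rmsd = float(np.sqrt(np.mean((diff - bias) ** 2)))
    if np.ptp(mea) == 0 or np.ptp(mod) == 0:
        slope, intercept = np.nan, np.nan
        r = p = np.nan
    else:
        res = sps.linregress(mea, mod)
        slope, intercept = float(res.slope), float(res.intercept)
        r, p = float(res.rvalue), float(res.pvalue)
    return ValidationStats(
        rmse=rmse, rmsd=rmsd, bias=bias, slope=slope, intercept=intercept,
        r=r, p=p, n=arr.shape[0],
    )
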