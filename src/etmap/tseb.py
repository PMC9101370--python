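"""Two-source energy balance with Priestley–Taylor initialization (TSEB-PT).

The surface is treated as two coupled sources — soil and canopy — with
separate temperatures, connected to the in-canopy air space by a series
resistance network. The radiometric temperature observed at nadir
constrains a weighted mix of the two component temperatures,

    T_rad^4 = f_theta * T_c^4 + (1 - f_theta) * T_s^4,

where ``f_theta`` is the vegetation fraction seen by the radiometer.
Canopy latent heat is initialized at the Priestley–Taylor equilibrium
rate (alpha_PT = 1.26 over the green canopy fraction); component
sensible heat fluxes follow from the series network; soil latent heat
is the residual of the soil balance. If the soil residual goes
negative (a non-physical condensation under daytime drying), alpha_PT
is reduced stepwise until it is non-negative — the model's signature
treatment of water-limited surfaces. The Obukhov length is iterated to
convergence with Monin–Obukhov stability corrections.

By construction every converged pixel closes the balance exactly:
``Rn = H + LE + G``.

Units: temperatures are degrees Celsius at interfaces and Kelvin
internally for radiative terms; fluxes W/m²; resistances s/m;
pressures hPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, replace

import numpy as np

from etmap.raster import Raster
from etmap.raster_prep import SurfaceInputs

SIGMA = 5.670374419e-8  # Stefan–Boltzmann, W/m²/K⁴
KARMAN = 0.4
GRAVITY = 9.81  # m/s²
R_DRY = 287.04  # gas constant of dry air, J/kg/K
CP_AIR = 1013.0  # specific heat of moist air, J/kg/K
EPS_MW = 0.622  # water/dry-air molecular weight ratio


@dataclass(frozen=True)
class MicrometRecord:
    """Tower micrometeorology driving a model run."""

    t_air: float  # °C
    wind: float  # m/s (floored at 0.1)
    pressure: float  # hPa
    e_a: float  # actual vapor pressure, hPa
    s_dn: float  # incoming solar radiation, W/m²
    z_u: float = 3.0  # wind measurement height, m
    z_t: float = 3.0  # temperature measurement height, m
    h_c: float = 0.3  # canopy height, m
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.s_dn < 0:
            raise ValueError("incoming solar radiation must be non-negative")
        if not 800.0 <= self.pressure <= 1100.0:
            raise ValueError("pressure outside plausible range 800..1100 hPa")
        object.__setattr__(self, "wind", max(float(self.wind), 0.1))


@dataclass(frozen=True)
class TSEBParameters:
    """Model constants; defaults are the classical documented choices."""

    alpha_pt: float = 1.26  # Priestley–Taylor coefficient
    kappa_s: float = 0.45  # net-radiation extinction coefficient through the canopy
    c_g: float = 0.35  # soil heat flux as a fraction of soil net radiation
    emis_canopy: float = 0.98
    emis_soil: float = 0.95
    albedo: float = 0.23
    z0m_ratio: float = 0.125  # z0m / h_c
    d_ratio: float = 0.65  # displacement height / h_c
    leaf_width: float = 0.1  # m
    rb_coeff: float = 90.0  # boundary-layer resistance coefficient C' (s/m)^(1/2) m^(-1/2)
    rs_a: float = 0.004  # soil-surface resistance: 1/(a + b*u_s)
    rs_b: float = 0.012
    max_iterations: int = 100
    l_tolerance: float = 1e-3  # relative convergence tolerance on Obukhov length
    alpha_step: float = 0.1  # stepwise alpha_PT reduction for drying soil

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_pt <= 2.0:
            raise ValueError("alpha_pt must lie in (0, 2]")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"{f.name} must be positive")


def saturation_vapor_pressure(t_air):
    """Saturation vapor pressure over water, hPa (Magnus/Tetens form)."""
    t = np.asarray(t_air, dtype=float)
    return 6.1078 * np.exp(17.269 * t / (t + 237.3))


def psychrometrics(t_air, pressure, e_a=0.0):
    """Thermodynamic support quantities at air temperature/pressure.

    Returns ``(delta, gamma, rho_air, c_p)``: the slope of the
    saturation vapor-pressure curve (hPa/K), the psychrometric constant
    ``gamma = c_p * P / (eps * lambda)`` (hPa/K), moist-air density
    (kg/m³) and the specific heat used (J/kg/K).
    """
    t = np.asarray(t_air, dtype=float)
    if np.any((t < -40.0) | (t > 60.0)):
        raise ValueError("air temperature outside supported range -40..60 °C")
    es = saturation_vapor_pressure(t)
    delta = es * 17.269 * 237.3 / (t + 237.3) ** 2
    lam = (2.501 - 0.00236 * t) * 1e6  # latent heat of vaporization, J/kg
    # gamma = cp*P/(eps*lambda); hPa in, hPa/K out (the 100 Pa/hPa factors cancel)
    gamma = CP_AIR * np.asarray(pressure, dtype=float) / (EPS_MW * lam)
    t_k = t + 273.15
    p_pa = np.asarray(pressure, dtype=float) * 100.0
    e_pa = np.asarray(e_a, dtype=float) * 100.0
    rho = (p_pa - (1.0 - EPS_MW) * e_pa) / (R_DRY * t_k)
    return delta, gamma, rho, CP_AIR


def longwave_down(t_air, e_a):
    """Clear-sky downwelling longwave radiation, W/m² (Brutsaert emissivity)."""
    t_k = np.asarray(t_air, dtype=float) + 273.15
    emis_atm = 1.24 * (np.asarray(e_a, dtype=float) / t_k) ** (1.0 / 7.0)
    return emis_atm * SIGMA * t_k**4


def view_fraction(lai, f_c):
    """Nadir-view vegetation fraction f_theta from LAI and cover."""
    lai = np.asarray(lai, dtype=float)
    f_c = np.clip(np.asarray(f_c, dtype=float), 1e-6, 1.0)
    f = f_c * (1.0 - np.exp(-0.5 * lai / f_c))
    return np.clip(np.where(lai > 0, f, 0.0), 0.0, 1.0 - 1e-3)


def partition_radiation(s_dn, t_air, t_rad, e_a, lai, params: TSEBParameters, f_c=1.0):
    """Net radiation and its soil/canopy split.

    ``Rn = (1 - albedo) * S_dn + eps * (L_dn - sigma * T_rad^4)`` with
    the surface emissivity mixed from canopy and soil by the view
    fraction; the soil share decays exponentially through the canopy,
    ``Rn_soil = Rn * exp(-kappa_s * LAI)``.
    Returns (Rn, Rn_canopy, Rn_soil), W/m².
    """
    lai = np.asarray(lai, dtype=float)
    t_rad_k = np.asarray(t_rad, dtype=float) + 273.15
    f_theta = view_fraction(lai, f_c)
    emis = f_theta * params.emis_canopy + (1.0 - f_theta) * params.emis_soil
    l_dn = longwave_down(t_air, e_a)
    rn = (1.0 - params.albedo) * np.asarray(s_dn, dtype=float) + emis * (
        l_dn - SIGMA * t_rad_k**4
    )
    rn_soil = rn * np.exp(-params.kappa_s * lai)
    return rn, rn - rn_soil, rn_soil


def _psi_m(zeta):
    """Integrated Monin–Obukhov stability correction for momentum."""
    zeta = np.clip(np.asarray(zeta, dtype=float), -10.0, 2.0)
    psi = np.where(zeta >= 0, -5.0 * zeta, 0.0)
    unstable = zeta < 0
    if np.any(unstable):
        x = (1.0 - 16.0 * np.where(unstable, zeta, 0.0)) ** 0.25
        psi_u = (
            2.0 * np.log((1.0 + x) / 2.0)
            + np.log((1.0 + x**2) / 2.0)
            - 2.0 * np.arctan(x)
            + np.pi / 2.0
        )
        psi = np.where(unstable, psi_u, psi)
    return psi


def _psi_h(zeta):
    """Integrated Monin–Obukhov stability correction for heat."""
    zeta = np.clip(np.asarray(zeta, dtype=float), -10.0, 2.0)
    psi = np.where(zeta >= 0, -5.0 * zeta, 0.0)
    unstable = zeta < 0
    if np.any(unstable):
        x = (1.0 - 16.0 * np.where(unstable, zeta, 0.0)) ** 0.25
        psi = np.where(unstable, 2.0 * np.log((1.0 + x**2) / 2.0), psi)
    return psi


def resistances(wind, z_u, z_t, h_c, lai, inv_l, params: TSEBParameters):
    """Series-network resistances (R_a, R_x, R_s) in s/m.

    ``inv_l`` is the inverse Obukhov length 1/L (0 = neutral; non-finite
    values fall back to neutral). R_a is the aerodynamic resistance from
    the log profile with stability corrections; R_x the bulk canopy
    boundary-layer resistance; R_s the soil-surface resistance from the
    wind speed just above the soil.
    """
    wind = max(float(wind), 0.1)
    inv_l = np.asarray(inv_l, dtype=float)
    inv_l = np.where(np.isfinite(inv_l), inv_l, 0.0)
    d = params.d_ratio * h_c
    z0m = params.z0m_ratio * h_c
    z0h = z0m
    if z_u <= d or z_t <= d:
        raise ValueError("measurement heights must exceed the displacement height")
    lai_f = np.maximum(np.asarray(lai, dtype=float), 1e-2)

    ln_u = np.log((z_u - d) / z0m)
    ln_t = np.log((z_t - d) / z0h)
    psi_m_u = _psi_m((z_u - d) * inv_l) - _psi_m(z0m * inv_l)
    psi_h_t = _psi_h((z_t - d) * inv_l) - _psi_h(z0h * inv_l)
    # keep the corrected profiles positive (strongly stable guard)
    denom_m = np.maximum(ln_u - psi_m_u, 0.1 * ln_u)
    denom_h = np.maximum(ln_t - psi_h_t, 0.1 * ln_t)
    u_star = KARMAN * wind / denom_m
    r_a = denom_h / (KARMAN * u_star)

    # wind at canopy top and its exponential decay inside the canopy
    u_c = np.maximum((u_star / KARMAN) * np.log((h_c - d) / z0m), 0.1)
    a_ext = 0.28 * lai_f ** (2.0 / 3.0) * h_c ** (1.0 / 3.0) * params.leaf_width ** (-1.0 / 3.0)
    u_d = u_c * np.exp(-a_ext * (1.0 - (d + z0m) / h_c))
    u_s = u_c * np.exp(-a_ext * (1.0 - 0.05 / h_c)) if h_c > 0.05 else u_c
    r_x = (params.rb_coeff / lai_f) * np.sqrt(params.leaf_width / np.maximum(u_d, 1e-3))
    r_s = 1.0 / (params.rs_a + params.rs_b * np.maximum(u_s, 1e-3))
    r_x = np.minimum(r_x, 5000.0)
    r_s = np.minimum(r_s, 5000.0)
    return r_a, r_x, r_s, u_star


def _solve_soil_temperature(t_rad_k, f_theta, a_lin, b_lin):
    """Newton solve of f_theta*(a + b*T_s)^4 + (1-f_theta)*T_s^4 = T_rad^4.

    The left side is strictly increasing in T_s for positive
    temperatures, so Newton from T_s = T_rad converges quadratically.
    """
    t_s = np.array(t_rad_k, dtype=float, copy=True)
    target = t_rad_k**4
    for _ in range(50):
        t_c = a_lin + b_lin * t_s
        f = f_theta * t_c**4 + (1.0 - f_theta) * t_s**4 - target
        fp = 4.0 * f_theta * b_lin * t_c**3 + 4.0 * (1.0 - f_theta) * t_s**3
        step = f / np.maximum(fp, 1e-12)
        t_s = t_s - step
        if np.all(np.abs(step) < 1e-9):
            break
    return t_s


def _tseb_pt_arrays(t_rad, lai, f_c, f_g, met: MicrometRecord, params: TSEBParameters):
    """Vectorized TSEB-PT over arrays; returns dict of flux arrays."""
    t_rad = np.asarray(t_rad, dtype=float)
    lai = np.broadcast_to(np.asarray(lai, dtype=float), t_rad.shape).copy()
    f_c = np.broadcast_to(np.asarray(f_c, dtype=float), t_rad.shape).copy()
    f_g = np.broadcast_to(np.asarray(f_g, dtype=float), t_rad.shape).copy()
    valid = np.isfinite(t_rad) & np.isfinite(lai) & np.isfinite(f_c) & np.isfinite(f_g)
    lai = np.where(valid, lai, 0.0)
    f_c = np.where(valid, f_c, 1.0)
    f_g = np.where(valid, f_g, 1.0)
    t_rad_fill = np.where(valid, t_rad, met.t_air)

    delta, gamma, rho, c_p = psychrometrics(met.t_air, met.pressure, met.e_a)
    t_a_k = met.t_air + 273.15
    t_rad_k = t_rad_fill + 273.15
    f_theta = view_fraction(lai, f_c)
    rn, rn_c, rn_s = partition_radiation(
        met.s_dn, met.t_air, t_rad_fill, met.e_a, lai, params, f_c=f_c
    )
    g_flux = params.c_g * rn_s
    pt_frac = f_g * delta / (delta + gamma)

    inv_l = np.zeros_like(t_rad_k)  # start neutral
    converged = np.zeros(t_rad_k.shape, dtype=bool)
    h = np.zeros_like(t_rad_k)
    le_c = np.zeros_like(t_rad_k)
    le_s = np.zeros_like(t_rad_k)
    h_c = np.zeros_like(t_rad_k)
    h_s = np.zeros_like(t_rad_k)
    alpha_used = np.full(t_rad_k.shape, params.alpha_pt)

    n_alpha = int(np.ceil(params.alpha_pt / params.alpha_step)) + 1
    for _ in range(params.max_iterations):
        r_a, r_x, r_s, u_star = resistances(
            met.wind, met.z_u, met.z_t, met.h_c, lai, inv_l, params
        )
        alpha = np.full(t_rad_k.shape, params.alpha_pt)
        for _k in range(n_alpha):
            le_c = np.maximum(alpha * pt_frac * rn_c, 0.0)
            h_c = rn_c - le_c
            hc_term = h_c * r_x / (rho * c_p)
            d_sum = 1.0 / r_a + 1.0 / r_s
            a_lin = (t_a_k / r_a + hc_term / r_x) / d_sum + hc_term
            b_lin = (1.0 / r_s) / d_sum
            t_s = _solve_soil_temperature(t_rad_k, f_theta, a_lin, b_lin)
            t_ac = (a_lin - hc_term) + b_lin * t_s
            h_s = rho * c_p * (t_s - t_ac) / r_s
            le_s = rn_s - g_flux - h_s
            dry = (le_s < -1e-9) & (alpha > 0.0)
            if not np.any(dry):
                break
            alpha = np.where(dry, np.maximum(alpha - params.alpha_step, 0.0), alpha)
        # fully dry soil: no evaporation, sensible heat takes the residual
        still_neg = le_s < 0.0
        le_s = np.where(still_neg, 0.0, le_s)
        h_s = np.where(still_neg, rn_s - g_flux, h_s)
        alpha_used = alpha
        h = h_c + h_s

        with np.errstate(divide="ignore", invalid="ignore"):
            inv_l_new = -KARMAN * GRAVITY * h / (rho * c_p * u_star**3 * t_a_k)
        inv_l_new = np.where(np.isfinite(inv_l_new), inv_l_new, 0.0)
        scale = np.maximum(np.abs(inv_l), 1e-4)
        newly = np.abs(inv_l_new - inv_l) <= params.l_tolerance * scale
        # freeze pixels once converged so the result is elementwise —
        # a raster run equals independent per-pixel solves exactly
        update = ~converged & ~newly
        inv_l = np.where(update, 0.5 * inv_l + 0.5 * inv_l_new, inv_l)
        converged = converged | newly
        if np.all(converged):
            break

    le = le_c + le_s
    out = {
        "Rn": np.where(valid, rn, np.nan),
        "H": np.where(valid, h, np.nan),
        "LE": np.where(valid, le, np.nan),
        "G": np.where(valid, g_flux, np.nan),
        "converged": converged & valid,
        "alpha_pt": np.where(valid, alpha_used, np.nan),
        "T_soil": np.where(valid, t_s - 273.15, np.nan),
        "LE_soil": np.where(valid, le_s, np.nan),
        "LE_canopy": np.where(valid, le_c, np.nan),
        "H_soil": np.where(valid, h_s, np.nan),
        "H_canopy": np.where(valid, h_c, np.nan),
    }
    return out


def tseb_pt_pixel(t_rad, lai, f_c, f_g, met: MicrometRecord, params: TSEBParameters = None):
    """Solve one pixel; returns (Rn, H, LE, G, converged)."""
    params = params or TSEBParameters()
    if not np.isfinite(t_rad):
        raise ValueError("radiometric temperature must be finite")
    r = _tseb_pt_arrays(
        np.array([[float(t_rad)]]), lai, f_c, f_g, met, params
    )
    return (
        float(r["Rn"][0, 0]),
        float(r["H"][0, 0]),
        float(r["LE"][0, 0]),
        float(r["G"][0, 0]),
        bool(r["converged"][0, 0]),
    )


@dataclass
class FluxRaster:
    """Four co-registered flux bands plus a convergence flag band."""

    raster: Raster  # (4, H, W): Rn, H, LE, G in W/m²
    converged: Raster  # (H, W) uint8

    BAND_ORDER = ("Rn", "H", "LE", "G")

    def band(self, name: str) -> np.ndarray:
        return self.raster.values[self.BAND_ORDER.index(name)]


def run_tseb(inputs: SurfaceInputs, met: MicrometRecord, params: TSEBParameters = None) -> FluxRaster:
    """Run TSEB-PT over co-registered surface rasters.

    Nodata (NaN) in any input propagates to all flux bands;
    deterministic for identical inputs.
    """
    params = params or TSEBParameters()
    t_rad = np.asarray(inputs.t_rad.band(0), dtype=float)
    out = _tseb_pt_arrays(
        t_rad,
        inputs.lai.band(0),
        inputs.f_c.band(0),
        inputs.f_g.band(0),
        met,
        params,
    )
    stack = np.stack([out[b] for b in FluxRaster.BAND_ORDER])
    flux = Raster(
        values=stack, transform=inputs.t_rad.transform, crs=inputs.t_rad.crs, nodata=None
    )
    conv = Raster(
        values=out["converged"].astype(np.uint8),
        transform=inputs.t_rad.transform,
        crs=inputs.t_rad.crs,
    )
    return FluxRaster(raster=flux, converged=conv)


def read_run_config(path) -> TSEBParameters:
    """Read a ``key = value`` run-configuration text file.

    Absent keys keep their defaults; unknown keys raise a warning;
    unparseable values raise a format error naming the key.
    """
    defaults = TSEBParameters()
    known = {f.name: f.type for f in fields(TSEBParameters)}
    overrides = {}
    with open(path, "r", encoding="ascii") as f:
        for line in f:
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed configuration line: {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                warnings.warn(f"unknown configuration key {key!r} ignored", stacklevel=2)
                continue
            try:
                overrides[key] = int(value) if key == "max_iterations" else float(value)
            except ValueError:
                raise ValueError(f"cannot parse value for key {key!r}: {value!r}") from None
    return replace(defaults, **overrides)
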