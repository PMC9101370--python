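"""Synthetic flights, scenes and forward-modelled flux truth.

Every stage of the pipeline is testable offline: this module generates
temperature fields, pseudo-color encoded snapshots with their colorbar,
trigger event logs, 5 Hz post-processed position tracks, surface rasters
with known LAI/cover, and — through a forward run of the two-source
energy-balance equations — flux rasters whose truth is known by
construction. All generators are pure functions of (spec, seed).

The forward flux oracle deliberately solves a *different* unknown than
the pixel solver: it fixes the soil temperature field and root-finds
the canopy temperature consistent with the Priestley–Taylor canopy
flux, then synthesizes the radiometric temperature those components
imply. Running the solver on that radiometric field must recover the
constructed fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from etmap.raster import Affine, LocalTangentPlane, Raster
from etmap.raster_prep import SurfaceInputs
from etmap.thermal import (
    ColorScale,
    ThermalSnapshot,
    temperature_to_level,
    write_ppm,
)
from etmap.tseb import (
    FluxRaster,
    MicrometRecord,
    TSEBParameters,
    partition_radiation,
    psychrometrics,
    resistances,
    view_fraction,
    KARMAN,
    GRAVITY,
)
from etmap.geolocation import GPS_UTC_LEAP_SECONDS, format_gga
from etmap.validation import ECRecord, FootprintSpec, average_over_mask, footprint_disk


def _default_met() -> MicrometRecord:
    # typical clear mid-morning conditions at the grassland tower
    return MicrometRecord(
        t_air=25.0, wind=2.0, pressure=1010.0, e_a=12.0, s_dn=800.0,
        z_u=3.0, z_t=3.0, h_c=0.3,
    )


@dataclass(frozen=True)
class SceneSpec:
    """Parametric synthetic scene: geometry, surface fields, weather."""

    width: float = 40.0  # m
    height: float = 40.0  # m
    resolution: float = 0.08  # m/pixel, the thermal mosaic scale
    base_lat: float = 46.69
    base_lon: float = 19.60
    site_mode: str = "grassland"
    lai_max: float = 2.5
    n_patches: int = 6
    t_soil_offset: float = 6.0  # bare dry soil excess over air temperature, °C
    t_canopy_offset: float = 1.0
    seed: int = 0
    met: MicrometRecord = field(default_factory=_default_met)

    @property
    def shape(self) -> tuple[int, int]:
        return (int(round(self.height / self.resolution)),
                int(round(self.width / self.resolution)))

    def grid(self) -> Raster:
        """Empty raster on the scene grid (local metric CRS, north-up)."""
        h, w = self.shape
        transform = Affine.from_origin(0.0, self.height, self.resolution, self.resolution)
        return Raster(values=np.zeros((h, w)), transform=transform, crs="LOCAL")

    def projection(self) -> LocalTangentPlane:
        return LocalTangentPlane(self.base_lat, self.base_lon)


def lai_field(spec: SceneSpec) -> np.ndarray:
    """Smooth patchy LAI field in [0, lai_max] from Gaussian bumps."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    y, x = np.mgrid[0:h, 0:w]
    x = x * spec.resolution
    y = y * spec.resolution
    lai = np.zeros((h, w))
    for _ in range(spec.n_patches):
        cx, cy = rng.uniform(0, spec.width), rng.uniform(0, spec.height)
        sx = rng.uniform(0.1, 0.3) * spec.width
        amp = rng.uniform(0.5, 1.0) * spec.lai_max
        lai += amp * np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * sx**2)))
    return np.clip(lai, 0.0, spec.lai_max)


def make_color_scale(n: int = 239, mode: str = "gray", seed: int = 0) -> ColorScale:
    """Build a colorbar of n distinct colors with strictly increasing key.

    ``gray``: a monotone grayscale ramp (requires n <= 256);
    ``random``: seeded distinct random colors sorted by key;
    ``scrambled``: distinct random colors in arbitrary key order, for
    proving the color lookup does not rely on key monotonicity.
    """
    if not 2 <= n <= 256**3:
        raise ValueError("n must be between 2 and 256³")
    if mode == "gray":
        if n > 256:
            raise ValueError("grayscale ramp supports at most 256 levels")
        g = np.round(np.linspace(0, 255, n)).astype(np.uint8)
        colors = np.stack([g, g, g], axis=1)
        return ColorScale(colors=colors)
    rng = np.random.default_rng(seed)
    seen = set()
    out = []
    while len(out) < n:
        c = tuple(int(v) for v in rng.integers(0, 256, 3))
        if c not in seen:
            seen.add(c)
            out.append(c)
    colors = np.array(out, dtype=np.uint8)
    if mode == "random":
        keys = (256**3 - 1) * colors[:, 0].astype(np.int64) + (256**2 - 1) * colors[
            :, 1
        ].astype(np.int64) + 255 * colors[:, 2].astype(np.int64)
        colors = colors[np.argsort(keys)]
    elif mode != "scrambled":
        raise ValueError(f"unknown colorbar mode {mode!r}")
    return ColorScale(colors=colors)


def encode_snapshot(
    t_grid: np.ndarray,
    t_min: float,
    t_max: float,
    scale: ColorScale,
    snapshot_id: int = 0,
    timestamp: float = 0.0,
) -> ThermalSnapshot:
    """Encode a temperature grid as a pseudo-colored snapshot.

    Nearest-level quantization: decoding the result is within half a
    quantization step of the input everywhere.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < t_min) or np.any(t_grid > t_max):
        raise ValueError("temperatures outside the snapshot range")
    levels = temperature_to_level(t_grid, t_min, t_max, scale.n_levels)
    return ThermalSnapshot(
        pixels=scale.colors[levels], t_min=t_min, t_max=t_max, scale=scale,
        snapshot_id=snapshot_id, timestamp=timestamp,
    )


# -- surface temperature scene ---------------------------------------------


def scene_temperature(spec: SceneSpec) -> np.ndarray:
    """Radiometric-like surface temperature field of the scene, °C.

    Dense vegetation stays near air temperature, bare soil runs
    ``t_soil_offset`` warmer, with mild seeded spatial noise.
    """
    rng = np.random.default_rng(spec.seed + 1)
    lai = lai_field(spec)
    t_air = spec.met.t_air
    frac = lai / spec.lai_max
    t = t_air + spec.t_canopy_offset * frac + spec.t_soil_offset * (1.0 - frac)
    t += rng.normal(0.0, 0.15, size=t.shape)
    return t


# -- flight simulation ------------------------------------------------------


def _serpentine(t, width, height, speed, line_spacing):
    """Position (x, y) along a serpentine survey path at time(s) t."""
    t = np.asarray(t, dtype=float)
    s = speed * t  # arc length
    leg = width  # along-x pass length
    n_line = np.floor(s / (leg + line_spacing)).astype(int)
    rem = s - n_line * (leg + line_spacing)
    along = np.clip(rem, 0.0, leg)
    cross = np.clip(rem - leg, 0.0, line_spacing)
    x = np.where(n_line % 2 == 0, along, leg - along)
    y = np.minimum(n_line * line_spacing + cross, height)
    return x, y


@dataclass
class FlightSim:
    """File-backed synthetic flight plus its truth table."""

    out_dir: Path
    snapshot_paths: list
    colorbar_path: Path
    event_log_path: Path
    pos_path: Path
    truth: list  # dicts: snapshot_id, time_gps (s of day), lat, lon, x, y
    common_range: tuple
    scale: ColorScale


def simulate_flight(
    spec: SceneSpec,
    out_dir: str | Path,
    duration: float = 60.0,
    snapshot_interval: float = 1.9,
    track_rate: float = 5.0,
    frame_shape: tuple[int, int] = (48, 64),
    start_tod: float = 9 * 3600.0,  # GPS seconds-of-day
    speed: float = 5.0,
) -> FlightSim:
    """Emit a complete synthetic flight in the formats the pipeline reads.

    Snapshots every 1.9 s along a serpentine path, each autoscaled to
    its own frame min/max and written as P6 PPM with a shared colorbar
    strip; an event log line per snapshot (id, t_min, t_max, GGA
    sentence in UTC); a 5 Hz RTKLIB-style .pos track in GPS time
    covering all events; and a truth table of exact trigger positions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 2)
    proj = spec.projection()
    temp = scene_temperature(spec)
    scale = make_color_scale()
    colorbar_path = out_dir / "colorbar.ppm"
    scale.to_strip(colorbar_path)

    h, w = spec.shape
    fh, fw = frame_shape
    event_times = np.arange(0.0, duration, snapshot_interval)
    line_spacing = max(spec.height / max(int(duration * speed / spec.width), 1), 5.0)

    # 5 Hz track bracketing the event window
    dt = 1.0 / track_rate
    track_times = np.arange(-2.0, duration + 2.0 + dt / 2, dt)
    tx, ty = _serpentine(np.maximum(track_times, 0.0), spec.width, spec.height, speed, line_spacing)
    tlat, tlon = proj.inverse(tx, ty)
    theight = 60.0 + rng.normal(0.0, 0.05, size=len(track_times))
    qualities = np.where(rng.random(len(track_times)) < 0.9, 1, 2)

    pos_path = out_dir / "rover.pos"
    with open(pos_path, "w", encoding="ascii") as f:
        f.write("% program : RTKPOST synthetic\n")
        f.write("%  GPST  latitude(deg) longitude(deg)  height(m)   Q  ns   sdn(m)   sde(m)   sdu(m)\n")
        for i, t in enumerate(track_times):
            tod = start_tod + t
            hh, mm = int(tod // 3600), int(tod // 60) % 60
            ss = tod % 60
            f.write(
                f"2020/05/27 {hh:02d}:{mm:02d}:{ss:06.3f}  {tlat[i]:.9f}  {tlon[i]:.9f}"
                f"  {theight[i]:9.4f}   {qualities[i]}  12   0.0050   0.0050   0.0100\n"
            )

    snapshot_paths = []
    truth = []
    event_lines = []
    for sid, t in enumerate(event_times, start=1):
        x, y = _serpentine(t, spec.width, spec.height, speed, line_spacing)
        col = int(np.clip(x / spec.resolution, fw // 2, w - fw // 2 - 1))
        row = int(np.clip((spec.height - y) / spec.resolution, fh // 2, h - fh // 2 - 1))
        frame = temp[row - fh // 2 : row + fh // 2, col - fw // 2 : col + fw // 2]
        t_min = float(np.floor(frame.min() * 10) / 10)
        t_max = float(np.ceil(frame.max() * 10) / 10)
        if t_max <= t_min:
            t_max = t_min + 0.1
        snap = encode_snapshot(frame, t_min, t_max, scale, snapshot_id=sid)
        p = out_dir / f"snapshot_{sid:04d}.ppm"
        write_ppm(snap.pixels, p)
        snapshot_paths.append(p)
        tod_gps = start_tod + t
        lat, lon = proj.inverse(float(x), float(y))
        gga = format_gga(tod_gps - GPS_UTC_LEAP_SECONDS, lat, lon, 60.0)
        event_lines.append(f"{sid} {t_min:.1f} {t_max:.1f} {gga}\n")
        truth.append(
            {"snapshot_id": sid, "time_gps": tod_gps, "lat": lat, "lon": lon,
             "x": float(x), "y": float(y), "t_min": t_min, "t_max": t_max}
        )

    event_log_path = out_dir / "events.txt"
    with open(event_log_path, "w", encoding="ascii") as f:
        f.writelines(event_lines)

    common = (min(r["t_min"] for r in truth), max(r["t_max"] for r in truth))
    return FlightSim(
        out_dir=out_dir, snapshot_paths=snapshot_paths, colorbar_path=colorbar_path,
        event_log_path=event_log_path, pos_path=pos_path, truth=truth,
        common_range=common, scale=scale,
    )


# -- forward energy-balance oracle -----------------------------------------


def forward_fluxes(
    spec: SceneSpec, params: TSEBParameters | None = None
) -> tuple[SurfaceInputs, FluxRaster, dict]:
    """Construct a scene whose fluxes are known by construction.

    Fixes the soil temperature field, then solves (bisection in canopy
    temperature, fixed-point in Obukhov length) for the canopy state at
    which the canopy latent heat equals the Priestley–Taylor rate at
    the given ``alpha_pt``. The implied radiometric temperature field
    plus LAI/cover rasters form the model inputs; the component fluxes
    form the truth. Raises if the construction yields negative soil
    evaporation (no physical solution at these settings).
    """
    params = params or TSEBParameters()
    met = spec.met
    lai = lai_field(spec)
    grid = spec.grid()
    h, w = spec.shape
    if spec.site_mode == "grassland":
        f_c = np.ones((h, w))
        f_g = np.clip(lai / spec.lai_max * 0.8 + 0.2, 0.0, 1.0)
    else:
        f_c = np.clip(lai / spec.lai_max * 0.8 + 0.1, 0.0, 1.0)
        f_g = np.ones((h, w))

    delta, gamma, rho, c_p = psychrometrics(met.t_air, met.pressure, met.e_a)
    t_a_k = met.t_air + 273.15
    frac = lai / spec.lai_max
    t_s_k = t_a_k + spec.t_soil_offset * (1.0 - 0.5 * frac)  # soil always warm
    f_theta = view_fraction(lai, f_c)
    pt = params.alpha_pt * f_g * delta / (delta + gamma)

    def network(t_c_k, r_a, r_x, r_s):
        s_sum = 1.0 / r_a + 1.0 / r_x + 1.0 / r_s
        t_ac = (t_a_k / r_a + t_c_k / r_x + t_s_k / r_s) / s_sum
        h_c = rho * c_p * (t_c_k - t_ac) / r_x
        h_s = rho * c_p * (t_s_k - t_ac) / r_s
        return t_ac, h_c, h_s

    def radiative(t_c_k):
        t_rad_k = (f_theta * t_c_k**4 + (1.0 - f_theta) * t_s_k**4) ** 0.25
        rn, rn_c, rn_s = partition_radiation(
            met.s_dn, met.t_air, t_rad_k - 273.15, met.e_a, lai, params, f_c=f_c
        )
        return t_rad_k, rn, rn_c, rn_s

    inv_l = np.zeros((h, w))
    for _outer in range(params.max_iterations):
        r_a, r_x, r_s, u_star = resistances(
            met.wind, met.z_u, met.z_t, met.h_c, lai, inv_l, params
        )
        lo = np.full((h, w), t_a_k - 25.0)
        hi = np.maximum(t_s_k, t_a_k) + 25.0

        def mismatch(t_c_k):
            _, h_c, _ = network(t_c_k, r_a, r_x, r_s)
            _, _, rn_c, _ = radiative(t_c_k)
            return h_c - (1.0 - pt) * rn_c

        for _ in range(60):  # bisection: mismatch is increasing in T_c
            mid = 0.5 * (lo + hi)
            pos = mismatch(mid) > 0
            hi = np.where(pos, mid, hi)
            lo = np.where(pos, lo, mid)
        t_c_k = 0.5 * (lo + hi)

        t_rad_k, rn, rn_c, rn_s = radiative(t_c_k)
        t_ac, h_c, h_s = network(t_c_k, r_a, r_x, r_s)
        h_tot = h_c + h_s
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_l_new = -KARMAN * GRAVITY * h_tot / (rho * c_p * u_star**3 * t_a_k)
        inv_l_new = np.where(np.isfinite(inv_l_new), inv_l_new, 0.0)
        done = np.abs(inv_l_new - inv_l) <= params.l_tolerance * np.maximum(np.abs(inv_l), 1e-4)
        inv_l = 0.5 * inv_l + 0.5 * inv_l_new
        if np.all(done):
            break

    g_flux = params.c_g * rn_s
    le_c = rn_c - h_c
    le_s = rn_s - g_flux - h_s
    if np.any(le_s < -1e-6):
        raise ValueError(
            "forward construction yields negative soil evaporation; "
            "reduce t_soil_offset or alpha_pt"
        )
    le_s = np.maximum(le_s, 0.0)
    le = le_c + le_s

    transform, crs = grid.transform, grid.crs
    inputs = SurfaceInputs(
        t_rad=Raster(values=t_rad_k - 273.15, transform=transform, crs=crs),
        lai=Raster(values=lai, transform=transform, crs=crs),
        f_c=Raster(values=f_c, transform=transform, crs=crs),
        f_g=Raster(values=f_g, transform=transform, crs=crs),
    )
    stack = np.stack([rn, h_tot, le, g_flux])
    truth = FluxRaster(
        raster=Raster(values=stack, transform=transform, crs=crs),
        converged=Raster(values=np.ones((h, w), np.uint8), transform=transform, crs=crs),
    )
    extras = {
        "t_canopy": t_c_k - 273.15,
        "t_soil": t_s_k - 273.15,
        "le_canopy": le_c,
        "le_soil": le_s,
    }
    return inputs, truth, extras


def synth_ec_series(
    truth: FluxRaster,
    footprint: FootprintSpec,
    imbalance_fraction: float = 0.0,
    noise_sd: float = 0.0,
    n_records: int = 1,
    seed: int = 0,
    start_time: float = 9 * 3600.0,
) -> list[ECRecord]:
    """EC half-hour records consistent with disk averages of the truth.

    Measured LE is deflated by ``imbalance_fraction`` (the classic
    eddy-covariance under-closure); residual closure recovers the disk
    average exactly. Gaussian noise of ``noise_sd`` W/m² on the
    sensible heat propagates one-to-one into the closed latent heat.
    """
    rng = np.random.default_rng(seed)
    mask = footprint_disk(footprint, truth.raster)
    rn, _ = average_over_mask(truth.band("Rn"), mask)
    h, _ = average_over_mask(truth.band("H"), mask)
    le, _ = average_over_mask(truth.band("LE"), mask)
    g, _ = average_over_mask(truth.band("G"), mask)
    records = []
    for i in range(n_records):
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        records.append(
            ECRecord(
                time=start_time + 1800.0 * i,
                h_ec=h + eps,
                le_ec=le * (1.0 - imbalance_fraction),
                rn=rn,
                g=g,
                wind_direction=footprint.wind_direction,
                peak_distance=footprint.peak_distance,
            )
        )
    return records
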