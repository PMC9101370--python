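# Methods

## Pseudo-color thermal codec

Snapshot-mode thermal cameras export frames as 8-bit RGB images whose
colors index an ordered 239-entry colorbar; the darkest entry maps to
the frame's minimum temperature, the brightest to its maximum, and the
frame range is divided linearly over the 239 levels (divisor
`N−1 = 238`, endpoints inclusive). Colors are compared through the
scalar key

    key(R, G, B) = (256³−1)·R + (256²−1)·G + 255·B.

The coefficients are not positional base-256 digits, but the key is
nevertheless injective over all 8-bit triples: the B term is at most
255·255 = 65 025, strictly below the G coefficient 65 535, and the G+B
terms together reach at most 16 776 450, strictly below the R
coefficient 16 777 215. Attribution is therefore an exact dictionary
lookup; for mosaicked imagery, where seam blending produces
near-palette colors, the nearest key within a configurable tolerance
(default 3·255 key units) is accepted and anything farther becomes
nodata.

Because every frame autoscales its own range, a flight is harmonized by
re-encoding each frame against the common range
`(min of all T_min, max of all T_max)`: each pixel is decoded with its
frame range and assigned the level `round((T − T_lo)/(T_hi − T_lo)·238)`
(half rounds away from zero, so quantization error is symmetric). The
decode∘encode error is at most half a quantization step,
`span/(2·238)`; after rescaling the additional error is at most half a
*common-range* step. Snapshots are stored as binary P6 PPM (maxval
255); ASCII P3 is accepted on read. The colorbar travels as a separate
239×1 PPM strip per flight, which keeps the frames pure data. The test
palette is a monotone grayscale ramp — injectivity and ordering are all
the codec relies on — and a scrambled-palette mode exists to show the
lookup does not depend on key monotonicity. The frame min/max are
treated as exact isothermal extremes; if a camera clips them to display
limits, decoded temperatures inherit that bias.

## Trigger-event geotagging

The onboard logger writes one line per snapshot: serial number,
per-frame min/max temperature, and the GGA sentence current at trigger
time (checksum verified; `ddmm.mmmm` converted to decimal degrees).
The PPK track is an RTKLIB-style `.pos` file at 5 Hz with quality codes
Q = 1/2/5 mapped to fix/float/single; any other code is a format error
naming the line. Each event is joined to the *nearest-in-time* track
point — a pick, not an interpolation — with ties resolved to the
earlier point and a default tolerance of 0.2 s; for a track that covers
the events at 0.2 s spacing, the worst pick offset is 0.1 s. Solution
quality converts to the nominal accuracies fix 0.5 m / float 2 m /
single 10 m expected by the mosaicking software.

Clocks: event timestamps are NMEA (UTC) time, the track is GPS time;
both are reduced to seconds-of-day and bridged by a configurable
leap-second offset (default 18 s). Flights last minutes, so midnight
wrap is not handled. GCP distances use the haversine on a sphere of
radius 6 378 137 m — within sub-millimeter of a full geodesic at
field scales; lat/lon↔metric conversions use a local tangent-plane
(equirectangular) projection about the site, adequate to well under a
millimeter over a few hundred meters.

## Surface parameters

Two visible-band indices are supported, VI = (G−R)/(G+R) and
VARI = (G−R)/(G+R−B); byte imagery is normalized by 255 first and
zero-denominator pixels become nodata. LAI is an ordinary
least-squares line against ceptometer ground points, fitted separately
for both indices with the higher-R² fit retained (ties go to VARI, for
determinism); the map `slope·index + intercept` is clamped below at
zero. Index values at point locations are sampled as the mean of a
5×5-pixel window to avoid single-pixel noise. The green mask is
VARI > 0.05 by default. Cover fractions aggregate the fine-resolution
mask by the fraction of true sub-pixel centers per coarse cell; site
mode "grassland" fixes f_c ≡ 1 and estimates the green fraction, site
mode "cropland" fixes f_g ≡ 1 and estimates the cover. Continuous
rasters resample by block mean of source pixel centers, categorical by
nearest neighbor; both are nodata-aware.

## Two-source energy balance (TSEB-PT)

Per pixel, the surface is a soil source and a canopy source coupled to
the in-canopy air space by a series resistance network. Net radiation

    Rn = (1 − albedo)·S_dn + ε·(L_dn − σ·T_rad⁴),

with surface emissivity mixed from canopy (0.98) and soil (0.95) by
the nadir view fraction `f_θ = f_c·(1 − exp(−0.5·LAI/f_c))`, and
clear-sky downwelling longwave from a Brutsaert-type atmospheric
emissivity `1.24·(e_a/T_a)^{1/7}`. The soil share decays through the
canopy as `Rn_s = Rn·exp(−κ_s·LAI)` (κ_s = 0.45), ground heat flux is
`G = c_g·Rn_s` (c_g = 0.35).

The solve: (1) canopy latent heat starts at the Priestley–Taylor rate
`LE_c = α_PT·f_g·Δ/(Δ+γ)·Rn_c` with α_PT = 1.26, giving
`H_c = Rn_c − LE_c`; (2) with the series network the canopy temperature
is linear in the soil temperature once H_c is fixed, so the radiometric
constraint `T_rad⁴ = f_θ·T_c⁴ + (1−f_θ)·T_s⁴` becomes a monotone
quartic in T_s, solved by Newton from T_s = T_rad; (3) soil sensible
heat follows from the network and soil latent heat as the residual
`LE_s = Rn_s − G − H_s`; (4) if LE_s < 0, α_PT is reduced in steps of
0.1 — the model's treatment of drying, water-limited soil — and at
α_PT = 0 any remaining negative residual is zeroed with H_s taking the
balance; (5) the Obukhov length is updated from the total sensible heat
and the iteration repeats to a relative tolerance of 10⁻³ on 1/L
(damped successive substitution; a pixel's stability state freezes once
converged, which makes a raster run bitwise equal to independent
per-pixel solves). Every converged pixel closes `Rn = H + LE + G`
identically because LE is defined by the residual at both sources.

Resistances: aerodynamic R_a from the log profile with Businger–Dyer
stability corrections (ζ clipped to [−10, 2]); bulk canopy boundary
layer `R_x = (C'/LAI)·√(l_w/U_d)` with C' = 90, leaf width 0.1 m and
U_d the exponentially attenuated wind at the canopy source height; soil
surface `R_s = 1/(a + b·u_s)` with a = 0.004, b = 0.012 and u_s the
wind just above the soil. Roughness z0m = 0.125·h_c, displacement
d = 0.65·h_c, z0h = z0m. Wind is floored at 0.1 m/s; non-finite
Obukhov lengths fall back to neutral. All constants live in
`TSEBParameters` and can be overridden from a `key = value` run
configuration file. Temperatures are °C at interfaces and Kelvin
internally; view geometry is fixed at nadir (gimbal-held cameras).

## Validation

The eddy-covariance footprint is a 10 m diameter disk centered
`peak_distance` meters from the tower along the direction the wind
comes from (meteorological bearing, clockwise from north — the peak
lies upwind). A pixel belongs to the disk iff its center does; at 8 cm
resolution against a 10 m disk this is unbiased to well under 2%.
Modelled LE is the arithmetic mean over valid disk pixels. The
measured balance is closed by residual into latent heat,
`LE_closed = Rn − G − H_ec`, mirroring the model's own residual
definition of LE; H-side and Bowen-ratio closures are recognized names
that deliberately raise "not implemented". EC records match flights by
the half-hour averaging interval containing the flight midpoint.
Statistics: RMSE (root-mean-square difference), RMSD (scatter about the
mean bias, so RMSE² = bias² + RMSD²), OLS slope/intercept and Pearson
r/p.

## Synthetic data and what the tests show

The fixtures build scenes of 40 m × 40 m at 8 cm by default (16 m at
coarser resolution in unit tests, to keep per-pixel solves cheap —
sizes are stated in each test), with patchy Gaussian LAI fields up to
2.5 m²/m², typical clear mid-morning weather (T_air 25 °C, wind 2 m/s,
1010 hPa, e_a 12 hPa, S_dn 800 W/m²), a 5 m/s serpentine flight with
the 1.9 s snapshot cadence and a bracketing 5 Hz track, and soil
4–6 °C warmer than air. All generators are pure functions of
(spec, seed).

The forward flux oracle solves a *different* unknown than the pixel
solver: it fixes the soil temperature field and bisects on the canopy
temperature until the canopy flux equals the Priestley–Taylor rate,
then emits the radiometric temperature those components imply together
with the component fluxes. Recovery of that truth by the solver
(RMSE ≲ 0.01 W/m² per band, bounded at 5 W/m² in the tests to absorb
codec quantization in the end-to-end chain) demonstrates internal
consistency of the implementation — it does not validate the physics
against real eddy-covariance data, which requires field measurements
the synthetic scenes cannot stand in for. Likewise the synthetic scenes
have no sensor noise beyond additive Gaussian perturbations, no lens
distortion, no mosaicking seams beyond palette-exact tiles, and no
footprint-model error (the disk is the representation, not an
approximation of one).

## Numerical choices and limitations

- Rounding in re-encoding is half-away-from-zero; attribution ties
  between two equidistant keys go to the lower key.
- The Newton solve of the soil-temperature quartic runs to 1e-9 K.
- f_θ is capped at 0.999 so the radiometric decomposition stays
  solvable under closed canopies; LAI is floored at 0.01 inside
  resistance formulas (canopy fluxes vanish with Rn_c as LAI → 0, so
  the floor never surfaces in output).
- GeoTIFF I/O supports axis-aligned (north-up) transforms;
  `fit_alignment` produces a general affine for control-point
  alignment, applied before export.
- Held-out GCP summary statistics use the population standard
  deviation; which GCPs are held out is entirely caller-specified.
- The stable branch of the stability correction is the linear −5ζ
  form; strongly stable nights (ζ > 2) are outside the intended
  daytime-flight envelope.
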