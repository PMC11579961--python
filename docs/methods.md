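# Methods

## Model structure

The model treats an arbitrary volume of shallow water at each latitude
as a box in which coral calcification may occur. Daily calcification is

    G(φ, d) = G_max · f_light(E_z(φ, d)) · f_darkdays(φ) · f_temp(φ)

and yearly calcification is the plain sum of G over the 365-day model
year (no extra day-length weighting: day length is already encoded in
the insolation). G_max defaults to 1 and is dimensionless — the model
predicts *relative* calcification potential, and latitudinal profiles
are additionally reported as a percentage of the per-scenario maximum.

The three factors are deliberately minimal. `f_light` is the
tanh photosynthesis–irradiance response used widely in reef modelling;
it has a single parameter, the saturating intensity E_k. `f_darkdays`
and `f_temp` are step functions: the model does not attempt
species-resolved tolerance curves, only a binary habitat envelope.

## Solar forcing

Daily top-of-atmosphere insolation is computed from orbital geometry:
the mean solar longitude advances uniformly through the calendar year
(anchored to the vernal equinox at day 80) and is corrected to the true
longitude with the classical series solution of Kepler's equation to
third order in eccentricity. Declination, sunset hour angle
ω_s = arccos(−tan φ tan δ) (clamped for polar day/night), day length
24·ω_s/π, and the 24-h-mean TOA irradiance

    Q̄ = (S₀/π) · (d̄/d)² · (ω_s sin φ sin δ + cos φ cos δ sin ω_s)

follow. Defaults are the modern orbit: e = 0.0167, ε = 23.44°,
longitude of perihelion 282.95°, S₀ = 1361 W m⁻², a 365-day year with
no leap days. Equinoxes and solstices fall out of the orbital
longitude rather than being hard-coded, so the engine remains valid for
non-modern orbits within its invariants (e < 0.1). Milankovitch
time-variation is out of scope.

A 1-minute numerical integration of instantaneous irradiance over the
day agrees with the analytic daily mean to well under 0.5% (tested);
the same geometry gives the textbook S₀/π at the equinoctial equator.

## E_surface: daylight-mean PAR and the conversion factor

The model's working light variable, E_surface, is the
**daylight-hours-mean** PAR photon flux at the sea surface:

    E_surface(φ, d) = par_conversion · Q̄(φ, d) · 24 / day_length(φ, d)

(zero during polar night; the daylight mean tends continuously to zero
at the polar-night boundary because the sun then only grazes the
horizon). The daylight mean — rather than the 24-h mean — is the
quantity corals integrate over while photosynthesis is possible, and it
is the reading under which the model's dark-day fit is internally
consistent: the 24-h-mean curve at 51° is too strongly curved around
the winter solstice for any conversion factor to place the minimal
dark-day threshold at 105 µmol m⁻² s⁻¹ on a 5-unit grid *and* give a
26-day feasible tolerance, whereas the daylight-mean curve admits a
narrow factor window that does both.

`par_conversion` (default **0.4075 µmol J⁻¹**) is a single bulk factor
folding together the PAR fraction of shortwave (~0.43), the
energy-to-photon conversion (~4.6 µmol J⁻¹ of PAR) and mean
atmospheric, cloud and sea-surface losses. It was calibrated so that
the inverse dark-day fit at a 50° target cutoff returns
E_lim = 105 µmol m⁻² s⁻¹ with feasible tolerances 1–26 days — the
parameter pair inferred from the fossil reef record. The fit is
sensitive to this factor: the window reproducing both numbers is
[0.4069, 0.4081] µmol J⁻¹. Just below it the feasible tolerance
interval at E_lim = 105 lengthens (27–28 days), and below ~0.405 the
minimal E_lim drops to 100 with the interval collapsing toward a
single day; above the window the interval at 105 shortens (25 days at
0.409, 13 at 0.42) and beyond ~0.43 the minimal E_lim moves to 110.
The factor is exposed in `OrbitConfig` and echoed by the `fit` report
so this sensitivity is always visible.

## Dark days and the tolerance rule

A day at a latitude is dark when E_surface is **strictly below**
E_lim ("must reach" the threshold: reaching it suffices, and E_lim = 0
never produces dark days). The yearly dark-day count gates
calcification: more dark days than the tolerance ⇒ f_darkdays = 0;
a count *equal* to the tolerance is tolerated (the boundary belongs to
"tolerance"). Counting always uses surface PAR, never E_z.

Dark-day counts are monotone in E_lim everywhere. With latitude they
are zero up to an onset latitude and essentially monotone beyond it,
but not strictly so poleward of ~80°: the polar summer insolation
maximum makes midsummer daylight means *rise* again at the highest
latitudes, which can shave a single day off the count between adjacent
high latitudes. This never affects the poleward cutoff, which is
decided at the onset flank.

## Temperature scenarios

`f_temp` gates on two numbers per latitude: the coldest-month and
warmest-month mean SST, against a 16–36 °C envelope (both ends
conservative for reef corals as a group; species are not
distinguished). The gate is annual: a latitude is either thermally
habitable for the year or not.

Scenarios are zonal means by unsigned latitude. The synthetic
generator produces

    T(φ) = T_pole + (T_eq − T_pole) · cos^p(φ)

applied with a shared exponent p to the coldest- and warmest-month
endpoint pairs — a smooth, monotone, endpoint-exact emulation of
meridional SST gradients. Four presets are bundled (endpoints in °C,
coldest-month equator/pole, with the 16 °C crossing on the 1° grid):

| preset         | cold eq | cold pole | p    | 16 °C crossing |
|----------------|---------|-----------|------|----------------|
| modern-like    | 28      | −2        | 2.50 | 36° |
| eocene-x3-like | 30      | 2         | 1.95 | 46° |
| eocene-x6-like | 32      | 6         | 1.84 | 54° |
| eocene-x9-like | 38      | 10        | 1.40 | 71° |

The x6/x9 exponents were solved so the crossings fall at 54° and 71°,
the latitudes where winter temperature becomes limiting in the
corresponding Earth-system-model hothouse scenarios; the presets are
labelled emulations, not model output. Warmest-month endpoints are
chosen plausibly warm (x6: 38/10, x9: 42/16) without tuning the
heat-limitation latitudes; the real hothouse fields place the
summer-heat exclusion zone wider than these emulations do. What
passing tests on these presets show is that the *machinery* (crossing
detection, gating, interplay with the dark-day rule) is correct — not
that the emulations reproduce the 2-D structure, zonal asymmetries or
coastal sampling of real SST fields.

The file reader accepts per-latitude CSV
(`latitude, coldest_month_sst, warmest_month_sst`) or NetCDF (1-D
latitude coordinate, variable names configurable, Kelvin
auto-converted). Input spanning both hemispheres is folded onto
unsigned latitude by N/S averaging, then linearly interpolated to the
model grid; extrapolation is an error rather than a guess.

## The inverse fit

`fit_light_cutoff` scans the E_lim grid (default 20–400 step 5,
consistent with the printed resolution of the headline value) in
ascending order and returns the first E_lim for which some tolerance t
in 1–365 satisfies both

* exclusion: dark-day count > t at every latitude poleward of the
  target cutoff, and
* permission: dark-day count ≤ t at every latitude at or equatorward
  of it,

together with the full feasible tolerance interval at that E_lim. An
infeasible problem (e.g. a target inside the polar night zone with a
bounded tolerance range) returns an empty result, not an exception.
Temperature is assumed unlimiting during the fit, as the fit isolates
the light control.

## Numerical choices and degenerate inputs

* Latitude grid 0–90° inclusive at a configurable step (default 1°);
  the Southern Hemisphere is treated by symmetry.
* At the poles, ω_s is decided by the sign of sin φ sin δ (the
  arccos argument is ill-conditioned there).
* tanh saturates to exactly 1.0 in floating point for arguments ≳ 19;
  the mathematical bound f_light < 1 holds wherever it is representable.
* Profile normalization divides by the per-scenario maximum; an
  all-zero profile reports 0% everywhere rather than NaN.
* Limiting-factor labels: `cold`/`heat`/`dark_days` when exactly one
  gate closes, `multiple` when more than one does, `light` when all
  gates are open but yearly calcification is below 99% of the scenario
  maximum, else `none`. The 99% threshold is a labelling convention
  only; it does not feed back into any computed quantity.
* Sweeps iterate the Cartesian product of sorted axes, so results are
  independent of axis ordering; the `kpar_z` axis varies k_par at the
  configured habitat depth.

## Problem sizes

The full pipeline is small by construction: 91 latitudes × 365 days per
profile, 77 candidate thresholds in the default fit. The test suite
and the reproduction script each run in seconds; no down-scaling was
needed anywhere.

## Known limitations

* No atmosphere or cloud model: a single bulk conversion factor stands
  between TOA irradiance and sea-surface PAR, and its default encodes a
  calibration, not a radiative-transfer calculation.
* The modern orbit only; no Milankovitch variation, which
  underestimates light at orbital extremes.
* Binary temperature and darkness gates; no species-specific
  photoacclimation, no variable E_k with depth, no heterotrophic
  compensation during dark periods.
* Aragonite saturation state, nutrients and turbidity are deliberately
  outside the model's scope.
* Synthetic scenarios are 1-D zonal means; real reef habitat is coastal
  and longitudinally structured.
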