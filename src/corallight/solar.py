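"""Daily solar geometry and surface PAR forcing.

Everything downstream of this module is driven by a single quantity:
``E_surface``, the effective photosynthetically active photon flux
(µmol m⁻² s⁻¹) reaching the sea surface, resolved per day of the year
and per degree of latitude.  It is built from first principles:

1. the orbital position of the Earth for each calendar day (Kepler's
   equation handled through the classical series expansion relating mean
   and true solar longitude),
2. solar declination and the sunset hour angle ω_s, which give day
   length and the 24-hour-mean top-of-atmosphere (TOA) irradiance,
3. a single bulk conversion factor from daylight-mean TOA shortwave
   irradiance (W m⁻²) to sea-surface PAR photon flux (µmol m⁻² s⁻¹).

The engine assumes a fixed (by default modern) orbit; it is valid for
any orbital configuration within the stated invariants, but makes no
attempt to follow Milankovitch variation through time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OrbitConfig",
    "DailyInsolation",
    "solar_declination",
    "sunset_hour_angle",
    "day_length",
    "daily_mean_insolation",
    "daylight_mean_irradiance",
    "surface_par",
    "daily_insolation",
    "surface_par_series",
    "surface_par_table",
]


@dataclass(frozen=True)
class OrbitConfig:
    """Orbital/solar constants governing the insolation engine.

    Parameters
    ----------
    eccentricity : float
        Orbital eccentricity (dimensionless, ``0 <= e < 0.1``).
    obliquity_deg : float
        Axial tilt in degrees.
    lon_perihelion_deg : float
        Longitude of perihelion measured from the vernal equinox, in
        degrees (geocentric solar convention; ~283° for the modern
        orbit, placing perihelion in early January).
    solar_constant : float
        Total solar irradiance at 1 AU, W m⁻².
    days_per_year : int
        Length of the model year; no leap days.
    par_conversion : float
        Bulk factor converting daylight-mean TOA shortwave irradiance
        (W m⁻²) into effective sea-surface PAR photon flux
        (µmol m⁻² s⁻¹ per W m⁻², i.e. µmol J⁻¹).  Folds together the
        PAR fraction of shortwave, the quantum conversion
        (~4.6 µmol J⁻¹ of PAR) and mean atmospheric/sea-surface losses.
        The default is calibrated so the dark-day fit reproduces the
        fossil-record poleward cutoff; see ``docs/methods.md``.
    vernal_equinox_day : float
        Calendar day (1 = January 1) at which the mean solar longitude
        is anchored to the vernal equinox.  Equinoxes and solstices are
        then located by the orbital longitude, not hard-coded.
    """

    eccentricity: float = 0.0167
    obliquity_deg: float = 23.44
    lon_perihelion_deg: float = 282.95
    solar_constant: float = 1361.0
    days_per_year: int = 365
    par_conversion: float = 0.4075
    vernal_equinox_day: float = 80.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eccentricity < 0.1:
            raise ValueError("eccentricity must satisfy 0 <= e < 0.1")
        if not 0.0 < self.obliquity_deg < 90.0:
            raise ValueError("obliquity_deg must be in (0, 90)")
        if self.solar_constant <= 0:
            raise ValueError("solar_constant must be positive")
        if self.days_per_year <= 0:
            raise ValueError("days_per_year must be positive")
        if self.par_conversion <= 0:
            raise ValueError("par_conversion must be positive")

    @property
    def obliquity(self) -> float:
        """Obliquity in radians."""
        return float(np.deg2rad(self.obliquity_deg))


@dataclass(frozen=True)
class DailyInsolation:
    """Solar geometry and surface PAR for one (latitude, day) pair."""

    latitude: float            # degrees, positive north
    day: int                   # day of year, 1..days_per_year
    declination: float         # radians
    sunset_hour_angle: float   # radians, ω_s in [0, π]
    day_length: float          # hours
    toa_mean_irradiance: float  # W m⁻², 24-h mean
    surface_par: float         # µmol m⁻² s⁻¹, daylight-mean PAR


def _check_day(day, orbit: OrbitConfig):
    day = np.asarray(day, dtype=float)
    if np.any(day < 1) or np.any(day > orbit.days_per_year):
        raise ValueError(
            f"day of year must be in [1, {orbit.days_per_year}]"
        )
    return day


def _check_latitude(latitude):
    latitude = np.asarray(latitude, dtype=float)
    if np.any(np.abs(latitude) > 90.0):
        raise ValueError("latitude must be within [-90, 90] degrees")
    return latitude


def _true_longitude(day, orbit: OrbitConfig):
    """True solar longitude λ (radians from vernal equinox) per day.

    Uses the standard series solution of Kepler's equation: the mean
    longitude advances uniformly through the calendar year and is
    corrected to the true longitude with terms up to third order in the
    eccentricity.  The constant offset anchors the *true* longitude to
    zero at the vernal equinox day.
    """
    e = orbit.eccentricity
    w = np.deg2rad(orbit.lon_perihelion_deg)
    beta = np.sqrt(1.0 - e * e)
    # mean longitude of the vernal equinox relative to true longitude 0
    lam_m0 = -2.0 * (
        (e / 2.0 + e**3 / 8.0) * (1.0 + beta) * np.sin(-w)
        - (e**2 / 4.0) * (0.5 + beta) * np.sin(-2.0 * w)
        + (e**3 / 8.0) * (1.0 / 3.0 + beta) * np.sin(-3.0 * w)
    )
    lam_mean = lam_m0 + 2.0 * np.pi * (day - orbit.vernal_equinox_day) / orbit.days_per_year
    return (
        lam_mean
        + (2.0 * e - e**3 / 4.0) * np.sin(lam_mean - w)
        + 1.25 * e**2 * np.sin(2.0 * (lam_mean - w))
        + (13.0 / 12.0) * e**3 * np.sin(3.0 * (lam_mean - w))
    )


def _distance_factor(true_lon, orbit: OrbitConfig):
    """(mean distance / distance)² from the true anomaly."""
    e = orbit.eccentricity
    nu = true_lon - np.deg2rad(orbit.lon_perihelion_deg)
    return (1.0 + e * np.cos(nu)) ** 2 / (1.0 - e * e) ** 2


def solar_declination(day, orbit: OrbitConfig = OrbitConfig()):
    """Solar declination δ in radians for a day of the year.

    δ = arcsin(sin ε · sin λ) with ε the obliquity and λ the true solar
    longitude; |δ| ≤ ε, zero at the equinoxes, extremal at the
    solstices.
    """
    day = _check_day(day, orbit)
    lam = _true_longitude(day, orbit)
    dec = np.arcsin(np.sin(orbit.obliquity) * np.sin(lam))
    return dec if dec.ndim else float(dec)


def sunset_hour_angle(latitude, declination):
    """Sunset hour angle ω_s = arccos(−tan φ · tan δ), radians.

    Clamped to 0 during polar night and π during polar day.
    """
    latitude = _check_latitude(latitude)
    phi = np.deg2rad(latitude)
    x = -np.tan(phi) * np.tan(np.asarray(declination, dtype=float))
    ws = np.arccos(np.clip(np.nan_to_num(x, nan=0.0), -1.0, 1.0))
    # exactly at the poles -tan(φ)tan(δ) is ill-conditioned; the sign of
    # sin φ · sin δ decides between permanent night and permanent day
    polar = np.abs(np.cos(phi)) < 1e-12
    if np.any(polar):
        night = np.sin(phi) * np.sin(declination) < 0
        ws = np.where(polar, np.where(night, 0.0, np.pi), ws)
    return ws if ws.ndim else float(ws)


def day_length(sunset_angle):
    """Day length in hours from the sunset hour angle: 24·ω_s/π."""
    ws = np.asarray(sunset_angle, dtype=float)
    if np.any(ws < -1e-12) or np.any(ws > np.pi + 1e-12):
        raise ValueError("sunset hour angle must be in [0, pi]")
    hours = 24.0 * np.clip(ws, 0.0, np.pi) / np.pi
    return hours if hours.ndim else float(hours)


def daily_mean_insolation(latitude, day, orbit: OrbitConfig = OrbitConfig()):
    """24-hour-mean TOA irradiance (W m⁻²) at a latitude and day.

    Q̄ = (S₀/π) · (d̄/d)² · (ω_s sin φ sin δ + cos φ cos δ sin ω_s);
    zero during polar night; includes the Sun–Earth distance factor.
    """
    latitude = _check_latitude(latitude)
    day = _check_day(day, orbit)
    lam = _true_longitude(day, orbit)
    dec = np.arcsin(np.sin(orbit.obliquity) * np.sin(lam))
    ws = sunset_hour_angle(latitude, dec)
    phi = np.deg2rad(latitude)
    rho = _distance_factor(lam, orbit)
    q = (orbit.solar_constant / np.pi) * rho * (
        ws * np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.sin(ws)
    )
    q = np.maximum(q, 0.0)
    return q if np.ndim(q) else float(q)


def daylight_mean_irradiance(latitude, day, orbit: OrbitConfig = OrbitConfig()):
    """Daylight-hours-mean TOA irradiance (W m⁻²).

    The 24-h mean rescaled by 24 h / day length; zero during polar
    night.  Continuous at the polar-night boundary (the daylight mean
    tends to zero as the sun grazes the horizon).
    """
    latitude = _check_latitude(latitude)
    day = _check_day(day, orbit)
    lam = _true_longitude(day, orbit)
    dec = np.arcsin(np.sin(orbit.obliquity) * np.sin(lam))
    ws = np.asarray(sunset_hour_angle(latitude, dec))
    q24 = np.asarray(daily_mean_insolation(latitude, day, orbit))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(ws > 0.0, q24 * np.pi / ws, 0.0)
    return q if q.ndim else float(q)


def surface_par(irradiance, orbit: OrbitConfig = OrbitConfig()):
    """Convert TOA shortwave irradiance (W m⁻²) to PAR photon flux.

    Purely linear: ``irradiance * orbit.par_conversion``.  Applied to
    the daylight-mean irradiance this yields the model's E_surface.
    """
    irradiance = np.asarray(irradiance, dtype=float)
    if np.any(irradiance < 0):
        raise ValueError("irradiance must be non-negative")
    par = irradiance * orbit.par_conversion
    return par if par.ndim else float(par)


def daily_insolation(latitude: float, day: int,
                     orbit: OrbitConfig = OrbitConfig()) -> DailyInsolation:
    """Full solar-geometry record for one (latitude, day) pair."""
    dec = solar_declination(day, orbit)
    ws = sunset_hour_angle(latitude, dec)
    q24 = daily_mean_insolation(latitude, day, orbit)
    e_surf = surface_par(daylight_mean_irradiance(latitude, day, orbit), orbit)
    return DailyInsolation(
        latitude=float(latitude),
        day=int(day),
        declination=dec,
        sunset_hour_angle=ws,
        day_length=day_length(ws),
        toa_mean_irradiance=q24,
        surface_par=e_surf,
    )


def surface_par_series(latitude: float,
                       orbit: OrbitConfig = OrbitConfig()) -> np.ndarray:
    """E_surface (µmol m⁻² s⁻¹) for every day of the year at one latitude."""
    days = np.arange(1, orbit.days_per_year + 1)
    return surface_par(daylight_mean_irradiance(latitude, days, orbit), orbit)


def surface_par_table(latitudes, orbit: OrbitConfig = OrbitConfig()) -> np.ndarray:
    """E_surface on a (latitude, day) grid, shape (n_lat, days_per_year)."""
    latitudes = _check_latitude(latitudes)
    days = np.arange(1, orbit.days_per_year + 1)
    lat2 = latitudes[:, None] * np.ones_like(days, dtype=float)[None, :]
    day2 = np.ones_like(latitudes)[:, None] * days[None, :]
    return np.asarray(
        surface_par(daylight_mean_irradiance(lat2, day2, orbit), orbit)
    )
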