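"""Limitation functions: light saturation, dark-day tolerance, temperature.

Three dimensionless factors multiply the maximum calcification rate:

* ``f_light`` — a hyperbolic-tangent photosynthesis–irradiance response,
  tanh(E_z / E_k), of the light remaining at habitat depth after
  Lambert–Beer attenuation through the water column;
* ``f_darkdays`` — a step function that zeroes calcification when the
  yearly count of "dark days" (days whose surface PAR stays below the
  threshold E_lim) exceeds a population's darkness tolerance;
* ``f_temp`` — a step function permitting calcification only when the
  coldest-month mean SST stays at or above T_min and the warmest-month
  mean stays at or below T_max.

Boundary conventions (the equations are stated with strict
inequalities, so the boundaries need an explicit choice):

* a day is "dark" when surface PAR is *strictly below* E_lim — a day
  that reaches E_lim is not dark;
* a dark-day count *equal* to the tolerance is tolerated (f = 1);
* temperatures exactly at T_min / T_max permit calcification.

Dark days are always counted on surface PAR, never on the attenuated
flux at depth: a population could in principle migrate upward to escape
darkness at depth, so depth must not create dark days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "LightParams",
    "TemperatureEnvelope",
    "attenuate",
    "photic_depth",
    "f_light",
    "count_dark_days",
    "f_darkdays",
    "f_temp",
    "flux_to_daily_dose",
    "daily_dose_to_flux",
]

#: e-folding count at which 1% of surface light remains: exp(-4.6) ~ 0.01
PHOTIC_OPTICAL_DEPTH = 4.6


@dataclass(frozen=True)
class LightParams:
    """Light-related parameters of the calcification model.

    Parameters
    ----------
    e_k : float
        Saturating light intensity of the tanh response, µmol m⁻² s⁻¹.
    e_lim : float or None
        Dark-day threshold, µmol m⁻² s⁻¹.  ``None`` disables the
        dark-day rule entirely.
    k_par : float
        Diffuse PAR attenuation coefficient of the water column, m⁻¹.
    z : float
        Habitat depth, m.  The product ``k_par * z`` is the optical
        depth that controls light at the reef.
    tolerance_days : int or None
        Number of dark days per year a population tolerates.  ``None``
        disables the dark-day rule.
    """

    e_k: float = 50.0
    e_lim: Optional[float] = 105.0
    k_par: float = 0.05
    z: float = 15.0
    tolerance_days: Optional[int] = 26

    def __post_init__(self) -> None:
        if self.e_k <= 0:
            raise ValueError("e_k must be positive")
        if self.e_lim is not None and self.e_lim < 0:
            raise ValueError("e_lim must be non-negative")
        if self.k_par <= 0:
            raise ValueError("k_par must be positive")
        if self.z < 0:
            raise ValueError("z must be non-negative")
        if self.tolerance_days is not None and not 0 <= int(self.tolerance_days) <= 366:
            raise ValueError("tolerance_days must be within one year")

    @property
    def optical_depth(self) -> float:
        """Dimensionless k_par · z."""
        return self.k_par * self.z

    @property
    def dark_day_rule_active(self) -> bool:
        return self.e_lim is not None and self.tolerance_days is not None


@dataclass(frozen=True)
class TemperatureEnvelope:
    """Permissive SST envelope for calcification, °C."""

    t_min: float = 16.0
    t_max: float = 36.0

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be below t_max")


def attenuate(e_surface, k_par: float, z: float):
    """Lambert–Beer attenuation: E_z = E_surface · exp(−k_par · z)."""
    e_surface = np.asarray(e_surface, dtype=float)
    if np.any(e_surface < 0):
        raise ValueError("e_surface must be non-negative")
    if k_par <= 0:
        raise ValueError("k_par must be positive")
    if z < 0:
        raise ValueError("z must be non-negative")
    out = e_surface * np.exp(-k_par * z)
    return out if out.ndim else float(out)


def photic_depth(k_par: float) -> float:
    """Depth of the photic zone (1% light level): 4.6 / k_par metres."""
    if k_par <= 0:
        raise ValueError("k_par must be positive")
    return PHOTIC_OPTICAL_DEPTH / k_par


def f_light(e_z, e_k: float):
    """Light-saturation factor tanh(E_z / E_k) in [0, 1)."""
    if e_k <= 0:
        raise ValueError("e_k must be positive")
    e_z = np.asarray(e_z, dtype=float)
    if np.any(e_z < 0):
        raise ValueError("e_z must be non-negative")
    out = np.tanh(e_z / e_k)
    return out if out.ndim else float(out)


def count_dark_days(daily_surface_par, e_lim: float,
                    days_per_year: int = 365) -> int:
    """Number of days in the year whose surface PAR is below E_lim.

    Strict comparison: a day exactly reaching ``e_lim`` is not dark, so
    ``e_lim = 0`` always yields zero dark days.
    """
    series = np.asarray(daily_surface_par, dtype=float)
    if series.ndim != 1 or series.size != days_per_year:
        raise ValueError(
            f"daily series must have length {days_per_year}, got {series.size}"
        )
    if np.any(series < 0):
        raise ValueError("surface PAR values must be non-negative")
    if e_lim < 0:
        raise ValueError("e_lim must be non-negative")
    return int(np.count_nonzero(series < e_lim))


def f_darkdays(n_dark: int, tolerance_days: int) -> int:
    """Dark-day step function: 0 if the count exceeds the tolerance.

    Equality is tolerated: ``n_dark == tolerance_days`` returns 1.
    """
    if n_dark < 0 or tolerance_days < 0:
        raise ValueError("counts must be non-negative")
    return 0 if n_dark > tolerance_days else 1


def f_temp(t_winter: float, t_summer: float,
           envelope: TemperatureEnvelope = TemperatureEnvelope()) -> int:
    """Temperature step function over the coldest/warmest month means.

    Returns 1 iff ``t_min <= t_winter`` and ``t_summer <= t_max``.
    """
    if t_winter > t_summer:
        raise ValueError("t_winter cannot exceed t_summer")
    return 1 if (envelope.t_min <= t_winter and t_summer <= envelope.t_max) else 0


def flux_to_daily_dose(flux_umol: float, daylight_hours: float = 12.0) -> float:
    """Convert a sustained PAR flux (µmol m⁻² s⁻¹) to a daily dose.

    Returns mol m⁻² day⁻¹ for the flux sustained over ``daylight_hours``.
    """
    if flux_umol < 0 or daylight_hours < 0:
        raise ValueError("inputs must be non-negative")
    return flux_umol * daylight_hours * 3600.0 * 1e-6


def daily_dose_to_flux(dose_mol: float, daylight_hours: float = 12.0) -> float:
    """Convert a daily PAR dose (mol m⁻² day⁻¹) to the equivalent flux.

    Returns µmol m⁻² s⁻¹ assuming the dose is spread over
    ``daylight_hours``.
    """
    if dose_mol < 0 or daylight_hours <= 0:
        raise ValueError("dose must be non-negative, hours positive")
    return dose_mol * 1e6 / (daylight_hours * 3600.0)
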