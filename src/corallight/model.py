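"""The calcification box model: combining light and temperature limits.

Daily calcification in an arbitrary shallow-water volume is

    G(φ, d) = G_max · f_light(E_z) · f_darkdays(φ) · f_temp(φ)

with E_z the attenuated daylight-mean surface PAR at habitat depth.
Yearly calcification is the plain sum of daily G over the model year;
latitudinal profiles are reported both in G units and normalized to the
maximum over latitudes within the same scenario/configuration.

On top of the forward model this module provides parameter sweeps over
(E_k, k_par·z, E_lim, tolerance) and the inverse problem: finding the
smallest dark-day threshold E_lim for which some darkness tolerance
confines calcification equatorward of a target cutoff latitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .limitation import (
    LightParams,
    TemperatureEnvelope,
    attenuate,
    count_dark_days,
    f_darkdays,
    f_light,
    f_temp,
)
from .scenarios import TemperatureScenario
from .solar import OrbitConfig, surface_par_series, surface_par_table

__all__ = [
    "ModelConfig",
    "CalcificationProfile",
    "SweepResult",
    "FitResult",
    "daily_G",
    "yearly_profile",
    "poleward_cutoff",
    "sweep",
    "fit_light_cutoff",
]

#: yearly_pct below which an open-gated latitude is labelled light-limited
LIGHT_LIMITED_PCT = 99.0


@dataclass(frozen=True)
class ModelConfig:
    """Full configuration of the box model."""

    g_max: float = 1.0
    light: LightParams = field(default_factory=LightParams)
    envelope: TemperatureEnvelope = field(default_factory=TemperatureEnvelope)
    orbit: OrbitConfig = field(default_factory=OrbitConfig)
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")
        if self.grid_step <= 0 or 90.0 % self.grid_step > 1e-9:
            raise ValueError("grid_step must be positive and divide 90")

    @property
    def latitudes(self) -> np.ndarray:
        return np.arange(0.0, 90.0 + self.grid_step / 2, self.grid_step)


@dataclass(frozen=True)
class CalcificationProfile:
    """Yearly calcification per latitude for one configuration."""

    latitudes: np.ndarray
    yearly_G: np.ndarray
    yearly_pct: np.ndarray
    dark_days: np.ndarray          # integer count per latitude
    limiting_factor: np.ndarray    # labels: none/light/dark_days/cold/heat/multiple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "latitude": self.latitudes,
                "yearly_G": self.yearly_G,
                "yearly_pct": self.yearly_pct,
                "dark_days": self.dark_days,
                "limiting_factor": self.limiting_factor,
            }
        )


@dataclass(frozen=True)
class SweepResult:
    """Cutoff latitude and profile per parameter combination."""

    table: pd.DataFrame                      # one row per combination
    profiles: list                           # CalcificationProfile per row

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


@dataclass(frozen=True)
class FitResult:
    """Outcome of the E_lim / dark-day-tolerance fit."""

    target_cutoff: float
    e_lim: Optional[float]           # minimal feasible threshold, None if infeasible
    tolerance_min: Optional[int]
    tolerance_max: Optional[int]
    par_conversion: float            # conversion factor the fit was run under

    @property
    def feasible(self) -> bool:
        return self.e_lim is not None


def _limitation_factors(latitude: float, day: int, config: ModelConfig,
                        scenario: TemperatureScenario):
    """The three limitation factors at one (latitude, day)."""
    lp = config.light
    series = surface_par_series(latitude, config.orbit)
    e_z = attenuate(series[int(day) - 1], lp.k_par, lp.z)
    fl = f_light(e_z, lp.e_k)
    if lp.dark_day_rule_active:
        n_dark = count_dark_days(series, lp.e_lim, config.orbit.days_per_year)
        fd = f_darkdays(n_dark, lp.tolerance_days)
    else:
        fd = 1
    t_cold, t_warm = scenario.interp(latitude)
    ft = f_temp(float(t_cold), float(t_warm), config.envelope)
    return fl, fd, ft


def daily_G(latitude: float, day: int, config: ModelConfig,
            scenario: TemperatureScenario) -> float:
    """Daily calcification rate at one latitude and day of year.

    The product G_max · f_light · f_darkdays · f_temp; always within
    [0, G_max].
    """
    fl, fd, ft = _limitation_factors(latitude, day, config, scenario)
    return config.g_max * fl * fd * ft


def yearly_profile(config: ModelConfig,
                   scenario: TemperatureScenario) -> CalcificationProfile:
    """Yearly calcification per latitude on the model grid.

    Sums daily G over the model year at each latitude, normalizes to the
    profile maximum (100% at the best latitude whenever any latitude
    calcifies) and labels the limiting factor per latitude.
    """
    lp = config.light
    lats = config.latitudes
    par = surface_par_table(lats, config.orbit)            # (nlat, ndays)
    e_z = attenuate(par, lp.k_par, lp.z)
    fl = f_light(e_z, lp.e_k)                              # (nlat, ndays)

    if lp.dark_day_rule_active:
        dark = np.count_nonzero(par < lp.e_lim, axis=1)
        fd = (dark <= lp.tolerance_days).astype(float)
    else:
        dark = np.count_nonzero(par < (lp.e_lim if lp.e_lim is not None else 0.0),
                                axis=1)
        fd = np.ones(lats.size)

    t_cold, t_warm = scenario.interp(lats)
    cold_gate = t_cold < config.envelope.t_min
    heat_gate = t_warm > config.envelope.t_max
    ft = (~cold_gate & ~heat_gate).astype(float)

    yearly = config.g_max * fl.sum(axis=1) * fd * ft
    top = yearly.max()
    pct = 100.0 * yearly / top if top > 0 else np.zeros_like(yearly)

    labels = np.empty(lats.size, dtype=object)
    dark_gate = fd == 0
    n_gates = cold_gate.astype(int) + heat_gate.astype(int) + dark_gate.astype(int)
    for i in range(lats.size):
        if n_gates[i] >= 2:
            labels[i] = "multiple"
        elif dark_gate[i]:
            labels[i] = "dark_days"
        elif cold_gate[i]:
            labels[i] = "cold"
        elif heat_gate[i]:
            labels[i] = "heat"
        elif pct[i] < LIGHT_LIMITED_PCT:
            labels[i] = "light"
        else:
            labels[i] = "none"

    return CalcificationProfile(
        latitudes=lats,
        yearly_G=yearly,
        yearly_pct=pct,
        dark_days=dark.astype(int),
        limiting_factor=labels,
    )


def poleward_cutoff(profile: CalcificationProfile) -> Optional[float]:
    """Highest latitude with nonzero yearly calcification (None if all zero)."""
    nz = np.flatnonzero(profile.yearly_G > 0)
    if nz.size == 0:
        return None
    return float(profile.latitudes[nz[-1]])


def sweep(config: ModelConfig, scenario: TemperatureScenario,
          e_k_values: Sequence[float],
          kpar_z_values: Sequence[float],
          e_lim_values: Sequence[Optional[float]],
          tolerance_values: Sequence[Optional[int]]) -> SweepResult:
    """Run the model over the Cartesian product of parameter axes.

    The ``kpar_z`` axis varies the optical depth at the configured
    habitat depth (k_par = kpar_z / z).  Rows are ordered
    lexicographically over (e_k, kpar_z, e_lim, tolerance); results do
    not depend on the ordering of the input axes.
    """
    for axis, name in (
        (e_k_values, "e_k"),
        (kpar_z_values, "kpar_z"),
        (e_lim_values, "e_lim"),
        (tolerance_values, "tolerance_days"),
    ):
        if len(axis) == 0:
            raise ValueError(f"sweep axis {name!r} must not be empty")

    z = config.light.z if config.light.z > 0 else 15.0
    rows, profiles = [], []
    for e_k, kz, e_lim, tol in product(
        sorted(e_k_values),
        sorted(kpar_z_values),
        sorted(e_lim_values, key=lambda v: (v is not None, 0 if v is None else v)),
        sorted(tolerance_values, key=lambda v: (v is not None, 0 if v is None else v)),
    ):
        light = replace(config.light, e_k=e_k, k_par=kz / z, z=z,
                        e_lim=e_lim, tolerance_days=tol)
        prof = yearly_profile(replace(config, light=light), scenario)
        rows.append(
            {
                "e_k": e_k,
                "kpar_z": kz,
                "e_lim": e_lim,
                "tolerance_days": tol,
                "cutoff_latitude": poleward_cutoff(prof),
            }
        )
        profiles.append(prof)
    return SweepResult(table=pd.DataFrame(rows), profiles=profiles)


def fit_light_cutoff(config: ModelConfig, target_cutoff: float,
                     e_lim_grid: Optional[Sequence[float]] = None,
                     tolerance_range: Optional[range] = None) -> FitResult:
    """Fit the dark-day parameters to a target poleward cutoff latitude.

    Finds the smallest E_lim on the grid for which some tolerance in the
    range zeroes calcification (via the dark-day rule alone, i.e. under
    an unlimiting temperature) at every latitude poleward of
    ``target_cutoff`` while permitting every latitude at or equatorward
    of it.  Also returns the full interval of feasible tolerances at
    that E_lim.  An infeasible problem yields an empty result, not an
    exception.

    The fit depends only on the insolation/PAR configuration: a
    latitude is excluded when its yearly dark-day count exceeds the
    tolerance, and permitted when it does not.
    """
    if e_lim_grid is None:
        e_lim_grid = np.arange(20.0, 400.0 + 1e-9, 5.0)
    if tolerance_range is None:
        tolerance_range = range(1, config.orbit.days_per_year + 1)
    e_lim_grid = np.sort(np.asarray(list(e_lim_grid), dtype=float))
    if e_lim_grid.size == 0:
        raise ValueError("e_lim_grid must not be empty")
    tol_lo, tol_hi = min(tolerance_range), max(tolerance_range)

    lats = config.latitudes
    if not (lats[0] <= target_cutoff <= lats[-1]):
        raise ValueError("target_cutoff must lie within the latitude grid")
    par = surface_par_table(lats, config.orbit)
    equator_side = lats <= target_cutoff + 1e-9
    if np.all(equator_side):
        raise ValueError("target_cutoff must leave at least one poleward latitude")

    for e_lim in e_lim_grid:
        dark = np.count_nonzero(par < e_lim, axis=1)
        need_at_most = int(dark[equator_side].max())     # permit equator side
        need_more_than = int(dark[~equator_side].min())  # exclude poleward side
        lo = max(tol_lo, need_at_most)
        hi = min(tol_hi, need_more_than - 1)
        if lo <= hi:
            return FitResult(
                target_cutoff=float(target_cutoff),
                e_lim=float(e_lim),
                tolerance_min=int(lo),
                tolerance_max=int(hi),
                par_conversion=config.orbit.par_conversion,
            )
    return FitResult(
        target_cutoff=float(target_cutoff),
        e_lim=None,
        tolerance_min=None,
        tolerance_max=None,
        par_conversion=config.orbit.par_conversion,
    )
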