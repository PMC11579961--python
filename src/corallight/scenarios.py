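"""Sea-surface-temperature scenarios per latitude.

A scenario is a pair of meridional curves — coldest-month and
warmest-month mean SST — on an ascending 0–90° latitude grid.  Two
sources are supported:

* a synthetic generator producing smooth poleward-declining cos^p
  gradients, used as the test stand-in for Earth-system-model output
  (warm "hothouse" worlds) and for the modern climatology, and
* a reader for per-latitude SST files (CSV or NetCDF) exported from
  real climatologies or model runs.

Scenarios are zonal means by unsigned latitude: files that include
Southern-Hemisphere latitudes are folded onto 0–90° by averaging the
two hemispheres.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureScenario",
    "SyntheticGradientSpec",
    "synth_scenario",
    "crossing_latitude",
    "read_scenario",
    "write_scenario",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class TemperatureScenario:
    """Coldest- and warmest-month mean SST by unsigned latitude."""

    name: str
    latitudes: np.ndarray          # degrees, ascending within [0, 90]
    coldest_month_sst: np.ndarray  # °C
    warmest_month_sst: np.ndarray  # °C

    def __post_init__(self) -> None:
        lats = np.asarray(self.latitudes, dtype=float)
        cold = np.asarray(self.coldest_month_sst, dtype=float)
        warm = np.asarray(self.warmest_month_sst, dtype=float)
        if not (lats.shape == cold.shape == warm.shape) or lats.ndim != 1:
            raise ValueError("latitudes and SST arrays must be 1-D, equal length")
        if np.any(lats < 0) or np.any(lats > 90):
            raise ValueError("latitudes must lie within [0, 90]")
        if np.any(np.diff(lats) <= 0):
            raise ValueError("latitudes must be strictly ascending")
        if np.any(warm < cold - 1e-9):
            raise ValueError("warmest-month SST must be >= coldest-month SST")
        object.__setattr__(self, "latitudes", lats)
        object.__setattr__(self, "coldest_month_sst", cold)
        object.__setattr__(self, "warmest_month_sst", warm)

    def interp(self, latitude) -> tuple:
        """(coldest, warmest) SST linearly interpolated to a latitude.

        Extrapolation outside the scenario grid is an error.
        """
        latitude = np.asarray(latitude, dtype=float)
        if np.any(latitude < self.latitudes[0] - 1e-9) or np.any(
            latitude > self.latitudes[-1] + 1e-9
        ):
            raise ValueError(
                "latitude outside the scenario grid; extrapolation is not allowed"
            )
        cold = np.interp(latitude, self.latitudes, self.coldest_month_sst)
        warm = np.interp(latitude, self.latitudes, self.warmest_month_sst)
        return cold, warm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "latitude": self.latitudes,
                "coldest_month_sst": self.coldest_month_sst,
                "warmest_month_sst": self.warmest_month_sst,
            }
        )


@dataclass(frozen=True)
class SyntheticGradientSpec:
    """Endpoints and steepness of a synthetic cos^p SST gradient.

    T(φ) = T_pole + (T_eq − T_pole) · cos(φ)^p, applied separately to
    the coldest- and warmest-month endpoint pairs with a shared shape
    exponent p.
    """

    t_eq_cold: float
    t_pole_cold: float
    t_eq_warm: float
    t_pole_warm: float
    shape_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.shape_exponent <= 0:
            raise ValueError("shape_exponent must be positive")
        if self.t_eq_cold < self.t_pole_cold or self.t_eq_warm < self.t_pole_warm:
            raise ValueError("equatorial endpoints must be >= polar endpoints")
        if self.t_eq_warm < self.t_eq_cold or self.t_pole_warm < self.t_pole_cold:
            raise ValueError("warmest-month endpoints must be >= coldest-month")


def synth_scenario(spec: SyntheticGradientSpec, grid_step: float = 1.0,
                   name: str = "synthetic") -> TemperatureScenario:
    """Generate a smooth poleward-declining scenario from endpoint specs.

    The profile is exact at both endpoints and monotone non-increasing
    with latitude for any positive shape exponent.
    """
    if grid_step <= 0 or 90.0 % grid_step > 1e-9:
        raise ValueError("grid_step must be positive and divide 90")
    lats = np.arange(0.0, 90.0 + grid_step / 2, grid_step)
    shape = np.cos(np.deg2rad(lats)) ** spec.shape_exponent
    shape[-1] = 0.0  # cos(90°)^p exactly zero despite rounding
    cold = spec.t_pole_cold + (spec.t_eq_cold - spec.t_pole_cold) * shape
    warm = spec.t_pole_warm + (spec.t_eq_warm - spec.t_pole_warm) * shape
    return TemperatureScenario(name, lats, cold, warm)


def crossing_latitude(scenario: TemperatureScenario, threshold: float):
    """Lowest grid latitude where coldest-month SST drops below a threshold.

    Returns ``None`` when the coldest-month curve stays at or above the
    threshold everywhere (no poleward temperature limit on the grid).
    """
    below = scenario.coldest_month_sst < threshold
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return None
    return float(scenario.latitudes[idx[0]])


# ---------------------------------------------------------------------------
# Bundled presets
#
# cos^p emulations of the meridional coldest/warmest-month gradients used
# in the study: a modern-like climatology and three progressively warmer
# "hothouse" worlds.  Shape exponents are solved so that the 16 °C
# coldest-month crossing of the x6-like preset falls at 54° and that of
# the x9-like preset at 71° on the 1° grid (the temperature-limiting
# latitudes of the corresponding Earth-system-model scenarios); the
# x3-like preset crosses near 46° and the modern-like near 36°.  These
# are labelled emulations — smooth zonal-mean stand-ins, not model data.
# ---------------------------------------------------------------------------
PRESETS = {
    "modern-like": SyntheticGradientSpec(
        t_eq_cold=28.0, t_pole_cold=-2.0,
        t_eq_warm=29.5, t_pole_warm=0.5,
        shape_exponent=2.5,
    ),
    "eocene-x3-like": SyntheticGradientSpec(
        t_eq_cold=30.0, t_pole_cold=2.0,
        t_eq_warm=34.0, t_pole_warm=6.0,
        shape_exponent=1.95,
    ),
    "eocene-x6-like": SyntheticGradientSpec(
        t_eq_cold=32.0, t_pole_cold=6.0,
        t_eq_warm=38.0, t_pole_warm=10.0,
        shape_exponent=1.84,
    ),
    "eocene-x9-like": SyntheticGradientSpec(
        t_eq_cold=38.0, t_pole_cold=10.0,
        t_eq_warm=42.0, t_pole_warm=16.0,
        shape_exponent=1.40,
    ),
}


def preset(name: str, grid_step: float = 1.0) -> TemperatureScenario:
    """Instantiate a bundled scenario preset by name."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown scenario preset {name!r}; available: {sorted(PRESETS)}"
        )
    return synth_scenario(PRESETS[name], grid_step=grid_step, name=name)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("latitude", "coldest_month_sst", "warmest_month_sst")


def _fold_and_regrid(lats, cold, warm, name, grid_step=1.0):
    """Fold onto unsigned latitude (averaging hemispheres) and regrid."""
    order = np.argsort(lats)
    lats, cold, warm = lats[order], cold[order], warm[order]
    if np.any(lats < 0):
        folded = {}
        for la, co, wa in zip(np.abs(lats), cold, warm):
            folded.setdefault(round(float(la), 6), []).append((co, wa))
        lats = np.array(sorted(folded))
        cold = np.array([np.mean([p[0] for p in folded[la]]) for la in lats])
        warm = np.array([np.mean([p[1] for p in folded[la]]) for la in lats])
    target = np.arange(0.0, 90.0 + grid_step / 2, grid_step)
    if lats[0] > target[0] + 1e-9 or lats[-1] < target[-1] - 1e-9:
        raise ValueError(
            f"scenario latitudes cover [{lats[0]:g}, {lats[-1]:g}] but the "
            "model grid needs [0, 90]; extrapolation is not allowed"
        )
    cold_i = np.interp(target, lats, cold)
    warm_i = np.interp(target, lats, warm)
    return TemperatureScenario(name, target, cold_i, warm_i)


def read_scenario(path, format: str | None = None,
                  cold_var: str = "coldest_month_sst",
                  warm_var: str = "warmest_month_sst",
                  grid_step: float = 1.0) -> TemperatureScenario:
    """Read a per-latitude SST scenario from CSV or NetCDF.

    CSV files need columns ``latitude, coldest_month_sst,
    warmest_month_sst``.  NetCDF files need a 1-D latitude coordinate
    and two variables (names configurable); a ``units`` attribute of
    ``K`` is auto-converted to °C.  Input latitudes may span both
    hemispheres; they are folded onto unsigned latitude (N/S averaged)
    and interpolated linearly onto the model grid.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "netcdf" if path.endswith((".nc", ".nc4", ".cdf")) else "csv"
    name = os.path.splitext(os.path.basename(path))[0]

    if format == "csv":
        df = pd.read_csv(path, comment="#")
        missing = [c for c in ("latitude", cold_var, warm_var) if c not in df.columns]
        if missing:
            raise ValueError(
                f"scenario file {path} is missing column(s): {', '.join(missing)}"
            )
        lats = df["latitude"].to_numpy(float)
        cold = df[cold_var].to_numpy(float)
        warm = df[warm_var].to_numpy(float)
    elif format == "netcdf":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            lat_name = next(
                (n for n in ("latitude", "lat") if n in ds.coords or n in ds.variables),
                None,
            )
            if lat_name is None:
                raise ValueError(f"scenario file {path} is missing a latitude coordinate")
            missing = [v for v in (cold_var, warm_var) if v not in ds.variables]
            if missing:
                raise ValueError(
                    f"scenario file {path} is missing variable(s): {', '.join(missing)}"
                )
            lats = np.asarray(ds[lat_name].values, dtype=float)
            cold = np.asarray(ds[cold_var].values, dtype=float)
            warm = np.asarray(ds[warm_var].values, dtype=float)
            for arr, var in ((cold, cold_var), (warm, warm_var)):
                units = str(ds[var].attrs.get("units", "degC"))
                if units.lower() in ("k", "kelvin"):
                    arr -= 273.15
                elif units.lower() not in ("degc", "celsius", "c", "deg_c", "degrees_celsius"):
                    raise ValueError(f"variable {var} has unsupported units {units!r}")
    else:
        raise ValueError(f"unknown scenario format {format!r}")

    return _fold_and_regrid(lats, cold, warm, name, grid_step)


def write_scenario(scenario: TemperatureScenario, path,
                   format: str | None = None) -> None:
    """Write a scenario to CSV (default) or NetCDF."""
    path = os.fspath(path)
    if format is None:
        format = "netcdf" if path.endswith((".nc", ".nc4", ".cdf")) else "csv"
    if format == "csv":
        scenario.to_frame().to_csv(path, index=False)
    elif format == "netcdf":
        import xarray as xr

        ds = xr.Dataset(
            {
                "coldest_month_sst": ("latitude", scenario.coldest_month_sst,
                                      {"units": "degC"}),
                "warmest_month_sst": ("latitude", scenario.warmest_month_sst,
                                      {"units": "degC"}),
            },
            coords={"latitude": scenario.latitudes},
        )
        ds.to_netcdf(path, engine="scipy", format="NETCDF3_CLASSIC")
    else:
        raise ValueError(f"unknown scenario format {format!r}")
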