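"""Run configuration: YAML files, defaults, and resolution to model objects.

A run configuration is a flat key-value file with sections::

    orbit:
      eccentricity: 0.0167
      obliquity_deg: 23.44
      lon_perihelion_deg: 282.95
      solar_constant: 1361.0
      days_per_year: 365
      par_conversion: 0.4075
    light:
      e_k: 50.0
      e_lim: 105.0
      k_par: 0.05
      z: 15.0
      tolerance_days: 26
    envelope:
      t_min: 16.0
      t_max: 36.0
    model:
      g_max: 1.0
      grid_step: 1.0
    scenario: eocene-x6-like       # preset name or file path

Command-line flags override file values; unspecified keys fall back to
the documented defaults.  The model is fully deterministic, so a seed
is accepted but unused.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .limitation import LightParams, TemperatureEnvelope
from .model import ModelConfig
from .scenarios import PRESETS, TemperatureScenario, preset, read_scenario
from .solar import OrbitConfig

__all__ = ["RunConfig", "load_run_config", "resolve_scenario", "resolved_dict"]

_SECTION_TYPES = {
    "orbit": OrbitConfig,
    "light": LightParams,
    "envelope": TemperatureEnvelope,
}


@dataclass(frozen=True)
class RunConfig:
    """A resolved run: model configuration plus scenario source."""

    model: ModelConfig = field(default_factory=ModelConfig)
    scenario: Optional[str] = None     # preset name or file path
    out_dir: str = "."
    seed: int = 0                      # reserved; the model is deterministic
    verbosity: int = 1


def _build_section(name: str, values: dict):
    cls = _SECTION_TYPES[name]
    valid = cls.__dataclass_fields__
    unknown = set(values) - set(valid)
    if unknown:
        raise ValueError(
            f"unknown key(s) in section {name!r}: {', '.join(sorted(unknown))}"
        )
    try:
        return cls(**values)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid value in section {name!r}: {exc}") from exc


def load_run_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Load a YAML run configuration, applying flat overrides.

    ``overrides`` uses dotted keys (``light.e_lim``, ``scenario``);
    ``None`` values are ignored so CLI flags can be passed through
    unconditionally.
    """
    data: dict = {}
    if path is not None:
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")

    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if "." in key:
            section, sub = key.split(".", 1)
            data.setdefault(section, {})[sub] = value
        else:
            data[key] = value

    sections = {}
    for name in _SECTION_TYPES:
        raw = data.get(name, {})
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config section {name!r} must be a mapping")
        sections[name] = _build_section(name, raw)

    model_raw = data.get("model", {}) or {}
    model = ModelConfig(
        g_max=float(model_raw.get("g_max", 1.0)),
        light=sections["light"],
        envelope=sections["envelope"],
        orbit=sections["orbit"],
        grid_step=float(model_raw.get("grid_step", 1.0)),
    )
    return RunConfig(
        model=model,
        scenario=data.get("scenario"),
        out_dir=str(data.get("out_dir", ".")),
        seed=int(data.get("seed", 0)),
        verbosity=int(data.get("verbosity", 1)),
    )


def resolve_scenario(run: RunConfig) -> TemperatureScenario:
    """Resolve the run's scenario source (preset name or file path)."""
    if run.scenario is None:
        raise ValueError(
            "no scenario configured: set 'scenario' to a preset name "
            f"({', '.join(sorted(PRESETS))}) or a file path"
        )
    if run.scenario in PRESETS:
        return preset(run.scenario, grid_step=run.model.grid_step)
    return read_scenario(run.scenario, grid_step=run.model.grid_step)


def resolved_dict(run: RunConfig) -> dict:
    """Full resolved configuration as a plain dict (for logs/sidecars)."""
    m = run.model
    return {
        "orbit": {
            "eccentricity": m.orbit.eccentricity,
            "obliquity_deg": m.orbit.obliquity_deg,
            "lon_perihelion_deg": m.orbit.lon_perihelion_deg,
            "solar_constant": m.orbit.solar_constant,
            "days_per_year": m.orbit.days_per_year,
            "par_conversion": m.orbit.par_conversion,
            "vernal_equinox_day": m.orbit.vernal_equinox_day,
        },
        "light": {
            "e_k": m.light.e_k,
            "e_lim": m.light.e_lim,
            "k_par": m.light.k_par,
            "z": m.light.z,
            "tolerance_days": m.light.tolerance_days,
        },
        "envelope": {"t_min": m.envelope.t_min, "t_max": m.envelope.t_max},
        "model": {"g_max": m.g_max, "grid_step": m.grid_step},
        "scenario": run.scenario,
        "out_dir": run.out_dir,
        "seed": run.seed,
    }
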