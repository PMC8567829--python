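"""Structured config files (JSON or TOML) for the CLI layer.

A config file has optional sections mirroring the library's parameter
objects::

    {
      "model":        {... ModelParameters overrides ...},
      "concentrations": {"Tglu": 7.46, "Tgaba": 1.82},
      "hemodynamics": {... HemodynamicParameters overrides ...},
      "sweep":        {... SweepConfig fields ...}
    }

Every model constant is overridable; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

from .params import Concentrations, HemodynamicParameters, ModelParameters
from .sweep import SweepConfig

__all__ = ["load_config", "build_model_parameters", "build_concentrations",
           "build_hemodynamic_parameters", "build_sweep_config"]

_SECTIONS = {"model", "concentrations", "hemodynamics", "sweep"}


def load_config(path) -> dict:
    """Read a JSON (.json) or TOML (.toml) config file."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
    else:
        cfg = json.loads(path.read_text())
    unknown = set(cfg) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return cfg


def build_model_parameters(cfg: dict) -> ModelParameters:
    return ModelParameters().with_(**cfg.get("model", {}))


def build_concentrations(cfg: dict) -> Concentrations:
    section = dict(cfg.get("concentrations", {}))
    base = Concentrations()
    return Concentrations(
        Tglu=section.get("Tglu", base.Tglu),
        Tgaba=section.get("Tgaba", base.Tgaba),
    )


def build_hemodynamic_parameters(cfg: dict) -> HemodynamicParameters:
    section = cfg.get("hemodynamics", {})
    return dataclasses.replace(HemodynamicParameters(), **section)


def build_sweep_config(cfg: dict) -> SweepConfig:
    section = dict(cfg.get("sweep", {}))
    if "fc_band" in section and section["fc_band"] is not None:
        section["fc_band"] = tuple(section["fc_band"])
    if "meta_band" in section:
        section["meta_band"] = tuple(section["meta_band"])
    known = {f.name for f in dataclasses.fields(SweepConfig)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown sweep option(s): {sorted(unknown)}")
    return SweepConfig(**section)
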