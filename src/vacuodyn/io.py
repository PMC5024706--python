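"""Configuration handling, packaged reference data and report writers."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .model_core import ModelParameters, OsmoticProtocol, VacuoleGeometry

__all__ = [
    "ConfigError",
    "load_config",
    "load_reference_conditions",
    "load_default_protocol",
    "protocol_from_config",
    "geometry_from_config",
    "params_from_config",
    "provenance",
    "write_json_report",
]

#: keys accepted in a run configuration
CONFIG_KEYS = {
    "model",
    "Pf",
    "Ps",
    "Vb",
    "eps_star",
    "C0",
    "Ce_star",
    "B",
    "t_star",
    "t_switch",
    "t_end",
    "direction",
    "dt",
    "diameter_um",
    "area_mode",
    "seed",
    "n_starts",
    "models",
    "bounds",
    "pf_grid",
    "ps_grid",
    "n_records",
    "cv_pf",
    "cv_ratio",
    "diameter_um_sd",
    "pixel_scale",
    "diameter_sd",
    "sampling_interval",
    "duration",
    "label",
    "ph_star",
    "weighted",
}


class ConfigError(ValueError):
    """Invalid or unknown configuration content (CLI exit code 2)."""


def load_config(path) -> dict[str, Any]:
    """Load a YAML/JSON config mapping, rejecting unknown keys."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, Mapping):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return dict(cfg)


def load_reference_conditions() -> pd.DataFrame:
    """Packaged per-pH WS permeability table (reference analysis input)."""
    with resources.files("vacuodyn.data").joinpath("reference_conditions.csv").open("rb") as fh:
        return pd.read_csv(fh, comment="#")


def load_default_protocol() -> OsmoticProtocol:
    """Packaged standard hypo-osmotic perfusion protocol."""
    with resources.files("vacuodyn.data").joinpath("default_protocol.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    return OsmoticProtocol(**cfg)


def protocol_from_config(cfg: Mapping[str, Any]) -> OsmoticProtocol:
    base = load_default_protocol()
    kwargs = {
        key: cfg[key]
        for key in ("C0", "t_switch", "B", "t_star", "Ce_star", "t_end", "direction")
        if key in cfg
    }
    try:
        return OsmoticProtocol(
            **{
                "C0": base.C0,
                "t_switch": base.t_switch,
                "B": base.B,
                "t_star": base.t_star,
                "Ce_star": base.Ce_star,
                "t_end": base.t_end,
                "direction": base.direction,
                **kwargs,
            }
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def geometry_from_config(cfg: Mapping[str, Any]) -> VacuoleGeometry:
    try:
        return VacuoleGeometry.from_diameter_um(
            float(cfg.get("diameter_um", 40.0)), cfg.get("area_mode", "recomputed")
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def params_from_config(cfg: Mapping[str, Any], geometry: VacuoleGeometry) -> ModelParameters:
    if "model" not in cfg:
        raise ConfigError("config needs a 'model' key")
    try:
        return ModelParameters(
            model_id=str(cfg["model"]),
            Pf=float(cfg.get("Pf", 0.0)),
            Ps=float(cfg.get("Ps", 0.0)),
            Vb=float(cfg.get("Vb", 0.0)),
            eps_star=float(cfg.get("eps_star", 0.0)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def provenance(cfg: Mapping[str, Any] | None = None, seed: int | None = None) -> dict:
    """Provenance block echoed into every structured output."""
    block = {"package": "vacuodyn", "version": __version__}
    if cfg is not None:
        block["config"] = dict(cfg)
    if seed is not None:
        block["seed"] = seed
    return block


def write_json_report(path, payload: Mapping[str, Any]) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=float), encoding="utf-8")
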