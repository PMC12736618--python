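"""YAML/JSON experiment configuration.

One file describes a whole run: circuit components, sweep grid, plant
profile (Cole targets, lag, drift, noise), schedule parameters, acquisition
protocol and pipeline settings.  Scalar fields use SI units and carry the
same names as the corresponding dataclass fields, e.g.::

    circuit: {r_series: 10.0e3, l_tank: 30.0e-3, c_tank: 1.0e-9}
    sweep: {f_start: 20.0e3, f_stop: 249.0e3, f_step: 1.0e3, dwell: 1.0e-3}
    profile:
      dark_target:  {r0: 50.0e3, r_inf: 2.0e3, tau: 2.0e-6, alpha: 0.8}
      light_target: {r0: 35.0e3, r_inf: 2.0e3, tau: 1.6e-6, alpha: 0.8}
      tau_resp: 5.0
    experiment: {duration_min: 2880, sweeps_per_burst: 20, seed: 0}

Unknown keys are rejected with the offending path so typos surface early.
"""

from __future__ import annotations

import json
from dataclasses import fields as dc_fields
from pathlib import Path

import yaml

from .circuit import CircuitComponents, ColeLoadParameters, SweepConfig
from .dataio import AcquisitionConfig
from .preprocessing import SplitSpec
from .synth import PlantProfile, default_profile
from .evaluation import ExperimentConfig

__all__ = ["load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid experiment configuration, with the offending key path."""


def _build(cls, data: dict, path: str, nested=None):
    nested = nested or {}
    allowed = {f.name for f in dc_fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in allowed:
            raise ConfigError(f"{path}.{key}: unknown field for "
                              f"{cls.__name__}")
        if key in nested and isinstance(value, dict):
            value = _build(nested[key][0], value, f"{path}.{key}",
                          nested[key][1] if len(nested[key]) > 1 else None)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse a YAML or JSON experiment file into an ExperimentConfig."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a mapping")
    known = {"circuit", "sweep", "profile", "split", "experiment"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")

    comps = _build(CircuitComponents, raw.get("circuit", {}), "circuit")
    sweep = _build(SweepConfig, raw.get("sweep", {}), "sweep")
    prof_raw = dict(raw.get("profile", {}))
    targets = {}
    for side in ("dark_target", "light_target"):
        if side in prof_raw:
            targets[side] = _build(ColeLoadParameters, prof_raw.pop(side),
                                   f"profile.{side}")
    base = default_profile()
    profile = _build(
        PlantProfile,
        {"dark_target": targets.get("dark_target", base.dark_target),
         "light_target": targets.get("light_target", base.light_target),
         **prof_raw},
        "profile")
    split = _build(SplitSpec, raw.get("split", {}), "split")

    exp_raw = dict(raw.get("experiment", {}))
    allowed = {f.name for f in dc_fields(ExperimentConfig)} \
        - {"profile", "comps", "split"}
    unknown = set(exp_raw) - allowed
    if unknown:
        raise ConfigError(f"experiment: unknown fields {sorted(unknown)}")
    cfg = ExperimentConfig(profile=profile, comps=comps, split=split,
                           **exp_raw)
    if sweep != SweepConfig():
        # non-default grid: shadow the acquisition factory on this instance
        cfg.acquisition = lambda sw=sweep, c=cfg: AcquisitionConfig(  # type: ignore[method-assign]
            sweeps_per_burst=c.sweeps_per_burst, sweep=sw)
    return cfg
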