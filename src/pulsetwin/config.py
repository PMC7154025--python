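"""Structured run configuration.

A run is described by a YAML mapping with the blocks below; anything omitted
falls back to the tabulated presets, and unknown top-level keys are rejected
so typos fail loudly.  The same dictionary (plus the seed) is hashed into
every output artifact for provenance.

    preset: porcine | pericardial
    seed: 1
    fluid: {rho: 1.0, mu: 1.0}
    circuit: {r_c: ..., r_p: ..., c: ...}          # downstream Windkessel
    valve: {k_open: ..., k_close: ..., inertance: ..., eoa_cm2: ...}
    targets: {sv_mean: ..., sv_sd: ..., dp_mean: ..., dp_sd: ..., re_peak: ...}
    experiment: {n_cycles: 10, filter_cutoff_hz: 100.0}
    integration: {max_step: 1.0e-4, tol: 1.0e-3, max_cycles: 30, method: LSODA}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import yaml

from .circuit import RCRWindkessel
from .presets import PRESETS, WINDKESSELS, get_preset

__all__ = ["RunConfig", "load_config", "config_hash"]

_KNOWN_KEYS = {"preset", "seed", "fluid", "circuit", "valve", "targets",
               "experiment", "integration", "output_dir"}


@dataclasses.dataclass
class RunConfig:
    preset_name: str = "porcine"
    seed: int = 0
    output_dir: str = "results"
    fluid_overrides: dict = dataclasses.field(default_factory=dict)
    circuit_overrides: dict = dataclasses.field(default_factory=dict)
    valve_overrides: dict = dataclasses.field(default_factory=dict)
    target_overrides: dict = dataclasses.field(default_factory=dict)
    experiment_overrides: dict = dataclasses.field(default_factory=dict)
    integration: dict = dataclasses.field(default_factory=dict)
    raw: dict = dataclasses.field(default_factory=dict)

    def preset(self):
        base = get_preset(self.preset_name)
        updates = {}
        if self.fluid_overrides:
            updates["fluid"] = dataclasses.replace(base.fluid,
                                                   **self.fluid_overrides)
        key_map = {"sv_mean": "sv_mean", "sv_sd": "sv_sd", "dp_mean": "dp_mean",
                   "dp_sd": "dp_sd", "re_peak": "re_peak"}
        for k, v in self.target_overrides.items():
            if k not in key_map:
                raise KeyError(f"unknown target key {k!r}")
            updates[key_map[k]] = float(v)
        exp_keys = {"n_cycles", "filter_cutoff_hz", "filter_pressures",
                    "filter_flow", "flutter_freq_hz", "flutter_amp_frac"}
        for k, v in self.experiment_overrides.items():
            if k not in exp_keys:
                raise KeyError(f"unknown experiment key {k!r}")
            updates[k] = v
        updates["seed"] = self.seed
        return dataclasses.replace(base, **updates)

    def windkessel(self) -> RCRWindkessel:
        base = WINDKESSELS[self.preset_name]
        return dataclasses.replace(base, **self.circuit_overrides) \
            if self.circuit_overrides else base

    def hash(self) -> str:
        return config_hash(self.raw, self.seed)


def config_hash(raw: dict, seed: int) -> str:
    blob = json.dumps({"config": raw, "seed": seed}, sort_keys=True,
                      default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path=None, **cli_overrides) -> RunConfig:
    """Load a YAML run config, apply CLI overrides, reject unknown keys."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw)}")
    raw.update({k: v for k, v in cli_overrides.items() if v is not None})
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise KeyError(f"unknown config key(s): {sorted(unknown)}; "
                       f"known keys: {sorted(_KNOWN_KEYS)}")
    preset_name = raw.get("preset", "porcine")
    if preset_name not in PRESETS:
        raise KeyError(f"unknown preset {preset_name!r}; "
                       f"available: {sorted(PRESETS)}")
    return RunConfig(
        preset_name=preset_name,
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "results")),
        fluid_overrides=dict(raw.get("fluid", {})),
        circuit_overrides=dict(raw.get("circuit", {})),
        valve_overrides=dict(raw.get("valve", {})),
        target_overrides=dict(raw.get("targets", {})),
        experiment_overrides=dict(raw.get("experiment", {})),
        integration=dict(raw.get("integration", {})),
        raw=raw,
    )
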