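"""Configuration files, CSV serialization and provenance sidecars.

Run configurations are single YAML documents (JSON, being a YAML subset, is
accepted unchanged).  Unknown keys are rejected rather than silently
ignored, and every command echoes the fully resolved configuration next to
its outputs so a run can be regenerated bit-identically from its output
directory alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import KineticParameters, STATE_FIELDS
from .simulate import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    OxygenSchedule,
    Trajectory,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "read_config",
    "dump_config",
    "default_config_path",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "TRAJECTORY_COLUMNS",
]


def default_config_path() -> Path:
    """The annotated default configuration shipped with the package."""
    return Path(__file__).parent / "data" / "defaults.yaml"

#: Public CSV schema; column names and order are part of the contract.
TRAJECTORY_COLUMNS = (
    "t_h", *STATE_FIELDS, "hif_total", "k_form_applied",
)

_PROTOCOLS = {
    "steady": ("k_form",),
    "chase": ("t_end", "dt_out"),
    "hypoxia": ("k_form_hypoxic", "t_end", "dt_out"),
    "reoxygenate": ("k_form_hypoxic", "hypoxia_duration", "t_end_after", "dt_out"),
    "single_compartment": ("k_form_hypoxic", "hypoxia_duration", "t_end_after", "dt_out"),
}

# Optional constants have defaults; k_form_hypoxic defines the perturbation
# and must be stated explicitly in a config.
_PROTOCOL_DEFAULTS = {
    "steady": {"k_form": 1000.0},
    "chase": {"t_end": 6.0, "dt_out": 1.0 / 60.0},
    "hypoxia": {"t_end": 30.0, "dt_out": 0.01},
    "reoxygenate": {"hypoxia_duration": 30.0, "t_end_after": 30.0, "dt_out": 0.01},
    "single_compartment": {"hypoxia_duration": 30.0, "t_end_after": 30.0,
                           "dt_out": 0.01},
}


class ConfigError(ValueError):
    """Configuration is malformed; message names the offending field."""


@dataclass
class RunConfig:
    """Resolved run configuration.

    Fields
    ------
    parameters : overrides applied on top of the default rate constants.
    protocol : name of the protocol plus its constants (fully resolved).
    scenario : optional preset name or inline ``{kind, magnitude}`` mapping.
    seed : integer seed for every stochastic component.
    tolerances : integrator tolerances (rtol, atol).
    output_dir : where commands write their artifacts.
    """

    parameters: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=lambda: {"name": "steady", "k_form": 1000.0})
    scenario: object = None
    seed: int = 0
    tolerances: dict = field(
        default_factory=lambda: {"rtol": DEFAULT_RTOL, "atol": DEFAULT_ATOL}
    )
    output_dir: str = "out"

    def resolved_params(self) -> KineticParameters:
        try:
            params = KineticParameters.from_dict(self.parameters) if self.parameters \
                else KineticParameters()
        except Exception as exc:
            raise ConfigError(f"parameters: {exc}") from exc
        if self.scenario is not None:
            from .phenotypes import ScenarioSpec, apply_preset, apply_scenario
            if isinstance(self.scenario, str):
                try:
                    params = apply_preset(params, self.scenario)
                except KeyError as exc:
                    raise ConfigError(f"scenario: {exc.args[0]}") from exc
            elif isinstance(self.scenario, dict):
                unknown = set(self.scenario) - {"kind", "magnitude"}
                if unknown:
                    raise ConfigError(f"scenario: unknown key(s) {sorted(unknown)}")
                if "kind" not in self.scenario:
                    raise ConfigError("scenario: missing required key 'kind'")
                params = apply_scenario(params, ScenarioSpec(**self.scenario))
            else:
                raise ConfigError(
                    f"scenario must be a preset name or a mapping, got "
                    f"{type(self.scenario).__name__}"
                )
        return params

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _validate_config_dict(raw: dict) -> dict:
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    out = dict(raw)
    protocol = dict(out.get("protocol") or {"name": "steady"})
    name = protocol.pop("name", None)
    if name is None:
        raise ConfigError("protocol: missing required key 'name'")
    if name not in _PROTOCOLS:
        raise ConfigError(
            f"protocol: unknown name {name!r}; available: {sorted(_PROTOCOLS)}"
        )
    allowed = set(_PROTOCOLS[name])
    unknown = set(protocol) - allowed
    if unknown:
        raise ConfigError(f"protocol {name!r}: unknown key(s) {sorted(unknown)}")
    resolved = dict(_PROTOCOL_DEFAULTS[name])
    resolved.update(protocol)
    missing = allowed - set(resolved)
    if missing:
        raise ConfigError(f"protocol {name!r}: missing constant(s) {sorted(missing)}")
    for key, value in resolved.items():
        if not isinstance(value, (int, float)) or not np.isfinite(value):
            raise ConfigError(f"protocol {name!r}: constant {key!r} must be a finite "
                              f"number, got {value!r}")
    out["protocol"] = {"name": name, **resolved}

    tol = dict(out.get("tolerances") or {})
    unknown = set(tol) - {"rtol", "atol"}
    if unknown:
        raise ConfigError(f"tolerances: unknown key(s) {sorted(unknown)}")
    out["tolerances"] = {"rtol": tol.get("rtol", DEFAULT_RTOL),
                         "atol": tol.get("atol", DEFAULT_ATOL)}

    params = out.get("parameters") or {}
    if not isinstance(params, dict):
        raise ConfigError("parameters must be a mapping of name -> value")
    out["parameters"] = params

    if "seed" in out and not isinstance(out["seed"], int):
        raise ConfigError(f"seed must be an integer, got {out['seed']!r}")
    return out


def read_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    cfg = RunConfig(**_validate_config_dict(raw if raw is not None else {}))
    cfg.resolved_params()  # fail early on bad parameter values
    return cfg


def dump_config(config: RunConfig, path) -> None:
    """Write the fully resolved configuration (provenance sidecar)."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False, default_flow_style=False)
    )


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    """Write a trajectory with the canonical column schema.

    Floats are written with ``repr`` precision so a read-back round-trips to
    at least 15 significant digits; the decimal separator is always '.'.
    """
    frame = trajectory.to_frame()
    assert tuple(frame.columns) == TRAJECTORY_COLUMNS
    frame.to_csv(path, index=False, float_format="%.17g")


def read_trajectory_csv(path, params: KineticParameters | None = None) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory_csv`.

    The applied schedule is reconstructed from the ``k_form_applied``
    column; derived columns are recomputed, not trusted.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigError(f"{path}: missing column(s) {sorted(missing)}")
    times = frame["t_h"].to_numpy()
    states = frame[list(STATE_FIELDS)].to_numpy()
    kf = frame["k_form_applied"].to_numpy()
    breaks = [(float(times[0]), float(kf[0]))]
    for t, a, b in zip(times[1:], kf[:-1], kf[1:]):
        if a != b:
            breaks.append((float(t), float(b)))
    schedule = OxygenSchedule(tuple(breaks))
    return Trajectory(times, states, schedule, params or KineticParameters())
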