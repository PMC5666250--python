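"""Parameter/config file handling and report writers.

Parameter files are flat YAML or JSON mappings with exactly the eleven
keys Lambda, mu, p, theta, beta, eta, sigma1, sigma2, gamma, epsilon,
nu.  The schema is strict in both directions — unknown keys and missing
keys are fatal — to catch silently misspelled Greek-letter names.

JSON reports carry a ``schema_version`` field and serialize floats to
12 significant digits so repeated runs on one platform are
bit-comparable.  CSV output uses '.' decimals and a header row,
independent of locale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .model import PARAMETER_NAMES, Parameters, require_valid

__all__ = [
    "ConfigError",
    "RunConfig",
    "SCHEMA_VERSION",
    "read_params",
    "write_params",
    "read_config",
    "write_config",
    "write_report",
    "write_csv",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A malformed parameter or run-configuration file."""


def _load_mapping(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    elif path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        raise ConfigError(f"unsupported config extension {path.suffix!r} (use .yaml/.yml/.json)")
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return data


def read_params(path) -> Parameters:
    """Read and validate a strict eleven-key parameter file."""
    path = Path(path)
    data = _load_mapping(path)
    unknown = sorted(set(data) - set(PARAMETER_NAMES))
    if unknown:
        raise ConfigError(f"{path}: unknown parameter key(s): {', '.join(unknown)}")
    missing = sorted(set(PARAMETER_NAMES) - set(data))
    if missing:
        raise ConfigError(f"{path}: missing parameter key(s): {', '.join(missing)}")
    values = {}
    for key in PARAMETER_NAMES:
        raw = data[key]
        if isinstance(raw, bool) or not isinstance(raw, (int, float)):
            raise ConfigError(f"{path}: parameter {key} must be a number, got {raw!r}")
        values[key] = float(raw)
    return require_valid(Parameters(**values))


def write_params(params: Parameters, path) -> None:
    path = Path(path)
    data = params.as_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        raise ConfigError(f"unsupported config extension {path.suffix!r}")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved description of one CLI run.

    ``params`` is either a parameter-file path or ``fixture:<name>``;
    ``options`` holds the command-specific settings with all defaults
    materialized, so the config round-trips exactly.
    """

    command: str
    params: str
    options: dict = field(default_factory=dict)
    output: str | None = None
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        return asdict(self)


_RUNCONFIG_KEYS = {"command", "params", "options", "output", "log_level"}


def read_config(path) -> RunConfig:
    path = Path(path)
    data = _load_mapping(path)
    unknown = sorted(set(data) - _RUNCONFIG_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    for required in ("command", "params"):
        if required not in data:
            raise ConfigError(f"{path}: missing required config key: {required}")
    return RunConfig(
        command=str(data["command"]),
        params=str(data["params"]),
        options=dict(data.get("options") or {}),
        output=data.get("output"),
        log_level=str(data.get("log_level", "INFO")),
    )


def write_config(config: RunConfig, path) -> None:
    path = Path(path)
    data = config.as_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def _round_floats(obj):
    """Recursively format floats to 12 significant digits."""
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if hasattr(obj, "tolist"):
        return _round_floats(obj.tolist())
    return obj


def write_report(report: dict, path) -> None:
    """Write a JSON report with a schema-version stamp."""
    path = Path(path)
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update(_round_floats(report))
    path.write_text(json.dumps(payload, indent=2) + "\n")


def write_csv(frame, path) -> None:
    """Write a DataFrame as locale-independent CSV with a header row."""
    frame.to_csv(Path(path), index=False)
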