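"""Configuration files, CSV export and run manifests for the CLI."""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import yaml

from . import __version__
from .community import EcosystemConfig, gut_config, marine_config
from .exceptions import UsageError

__all__ = ["load_config", "write_manifest"]

_PRESETS = {"marine": marine_config, "gut": gut_config}

# EcosystemConfig fields a YAML config may override directly.
_SIMPLE_FIELDS = {"bacteria_range", "phage_range", "adsorption_range", "time_range",
                  "time_kind", "commitment_fraction", "noise_sd", "colon_volume_ml"}
# Keys forwarded to the preset factory (curve construction).
_FACTORY_KEYS = {"n_ranks", "phage_decay", "bacteria_decay"}


def load_config(ecosystem: str, config_path: str | Path | None = None,
                **factory_overrides) -> EcosystemConfig:
    """Build an :class:`EcosystemConfig` from a preset plus optional YAML overrides.

    The YAML file maps field names to values, e.g.::

        noise_sd: 0.05
        time_range: [2.74, 7.27]
        n_ranks: 100
        phage_decay: 0.8

    Unknown keys are rejected rather than silently ignored.
    """
    if ecosystem not in _PRESETS:
        raise UsageError(f"unknown ecosystem {ecosystem!r}; choose from {sorted(_PRESETS)}")
    overrides = {}
    if config_path is not None:
        with open(config_path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise UsageError(f"config file {config_path} must be a mapping")
        overrides = loaded
    factory_kwargs = {k: overrides.pop(k) for k in list(overrides) if k in _FACTORY_KEYS}
    bad_factory = set(factory_overrides) - _FACTORY_KEYS
    if bad_factory:
        raise UsageError(f"unknown factory overrides: {sorted(bad_factory)}")
    factory_kwargs.update(factory_overrides)  # explicit args beat the file
    bad = set(overrides) - _SIMPLE_FIELDS
    if bad:
        raise UsageError(f"unknown config keys: {sorted(bad)}")
    for key in ("bacteria_range", "phage_range", "adsorption_range", "time_range"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    return _PRESETS[ecosystem](**factory_kwargs, **overrides)


def write_manifest(out_path: str | Path, command: str, seed: int,
                   outputs: list, config_summary: dict | None = None) -> Path:
    """Write a JSON run manifest next to the outputs it describes."""
    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": int(seed),
        "outputs": [str(p) for p in outputs],
        "config": config_summary or {},
        "timestamp_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    path = Path(out_path)
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
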