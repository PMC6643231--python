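"""YAML configuration handling for the command-line interface.

A config file is a flat mapping of :class:`ExperimentConfig` field names
(plus ``R``/``V`` for mate search). Unknown keys are rejected by name, and
all validation errors identify the offending key. An empty file yields the
standard defaults (pool 100, colonize at 2, d=0.1, i=0.001, lognormal
growth rates, 1e7-event burn-in with 100 samples every 2e5 events).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .experiments import ExperimentConfig
from .rates import SearchParams

__all__ = ["ConfigError", "parse_config", "config_to_dict"]

_FIELD_NAMES = {f.name for f in dataclasses.fields(ExperimentConfig) if f.name != "search"}
_EXTRA_KEYS = {"R", "V"}


class ConfigError(ValueError):
    """A configuration file failed validation."""


def parse_config(path: str | Path | None = None, **overrides) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML file and/or overrides.

    ``R`` and ``V`` must be given together (they define a
    :class:`SearchParams`); omitting both means asexual taxa. Overrides
    with value ``None`` are ignored so CLI flags can pass through unset.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(raw) - _FIELD_NAMES - _EXTRA_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")

    has_R, has_V = "R" in raw, "V" in raw
    if has_R != has_V:
        raise ConfigError("mate search requires both R and V (one was given alone)")
    search = None
    if has_R:
        try:
            search = SearchParams(float(raw.pop("R")), float(raw.pop("V")))
        except ValueError as exc:
            raise ConfigError(f"invalid search parameters: {exc}") from exc

    try:
        return ExperimentConfig(search=search, **raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: ExperimentConfig) -> dict:
    """Flat JSON-serializable snapshot of a config (for run manifests)."""
    out = dataclasses.asdict(config)
    search = out.pop("search")
    if search is not None:
        out["R"] = search["R"]
        out["V"] = search["V"]
    return out
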