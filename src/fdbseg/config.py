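"""Flat YAML configuration for the pipeline.

A config file is a single flat mapping whose keys are the pipeline
parameters plus a few presentation options; unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .params import FDBParams

__all__ = ["RunConfig", "load_config", "save_config"]

_PARAM_KEYS = ("C", "n", "L", "gamma", "omega_L", "omega_H", "s", "t", "b", "pad", "variant")
_EXTRA_KEYS = ("threshold_kind", "invert_display", "verbosity")
_INT_KEYS = {"n", "L", "gamma", "s", "b", "pad"}


@dataclass
class RunConfig:
    """Pipeline parameters plus presentation options."""

    params: FDBParams = field(default_factory=FDBParams)
    threshold_kind: str = "soft"
    invert_display: bool = False
    verbosity: int = 0

    def to_dict(self) -> dict:
        out = {k: getattr(self.params, k) for k in _PARAM_KEYS}
        out.update(
            threshold_kind=self.threshold_kind,
            invert_display=self.invert_display,
            verbosity=self.verbosity,
        )
        return out


def load_config(path: str | Path) -> RunConfig:
    """Read a flat key-value YAML config; unknown keys raise ParameterError."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParameterError(f"config {path} must be a flat key-value mapping")
    unknown = set(data) - set(_PARAM_KEYS) - set(_EXTRA_KEYS)
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    param_kwargs = {}
    for k in _PARAM_KEYS:
        if k in data:
            param_kwargs[k] = int(data[k]) if k in _INT_KEYS else data[k]
    return RunConfig(
        params=FDBParams(**param_kwargs),
        threshold_kind=data.get("threshold_kind", "soft"),
        invert_display=bool(data.get("invert_display", False)),
        verbosity=int(data.get("verbosity", 0)),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the config as flat YAML (round-trips through load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
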