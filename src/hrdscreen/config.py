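"""Packaged default constants and helpers to load/override them.

All pipeline constants (gene panel, predictor list, drug categories,
methylation thresholds, scar-score lengths, association settings) live in
``data/defaults.yaml`` inside the installed package, so that every analysis
is reproducible from a single, inspectable file. ``load_defaults`` returns a
deep copy; callers may mutate the result freely.
"""

from __future__ import annotations

import copy
from importlib import resources
from typing import Any

import yaml

_CACHE: dict[str, Any] | None = None


def _read_packaged_yaml() -> dict[str, Any]:
    global _CACHE
    if _CACHE is None:
        text = resources.files("hrdscreen.data").joinpath("defaults.yaml").read_text()
        _CACHE = yaml.safe_load(text)
    return _CACHE


def load_defaults() -> dict[str, Any]:
    """Return a deep copy of the packaged default configuration."""
    return copy.deepcopy(_read_packaged_yaml())


def merged_config(overrides: dict[str, Any] | None = None) -> dict[str, Any]:
    """Packaged defaults with ``overrides`` merged in (nested dicts merge key-wise)."""
    cfg = load_defaults()
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict[str, Any], extra: dict[str, Any]) -> None:
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value


def packaged_data_path(name: str):
    """A traversable handle on a file under ``hrdscreen/data``."""
    return resources.files("hrdscreen.data").joinpath(name)
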