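"""Configuration: the shipped component registry and run-level settings.

The default registry (curve parameters, correlation design, keyword lists,
thresholds) lives in ``data/registry.yaml`` inside the package; user
configs override it key by key.
"""

from __future__ import annotations

import copy
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["default_config", "load_config", "merge_config"]


@lru_cache(maxsize=1)
def _shipped() -> dict:
    text = resources.files("rgscore").joinpath("data/registry.yaml").read_text()
    return yaml.safe_load(text)


def default_config() -> dict:
    """A deep copy of the shipped default configuration."""
    return copy.deepcopy(_shipped())


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict:
    """Recursively merge ``override`` into ``base`` (dicts merged, else replaced)."""
    out = copy.deepcopy(dict(base))
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file merged over the shipped defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = merge_config(cfg, user)
    return cfg
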