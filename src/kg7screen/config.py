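"""Run configuration: packaged defaults plus user overrides (JSON/YAML)."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config"]


def default_config() -> dict:
    """The packaged default configuration (selection rule, thresholds,
    reference definition, cut-off constraint)."""
    with resources.files("kg7screen.data").joinpath("default_config.json").open() as fh:
        return json.load(fh)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults deep-merged with a JSON or YAML override file."""
    cfg = default_config()
    if path is None:
        return cfg
    text = Path(path).read_text()
    override = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(override, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _deep_merge(cfg, override)
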