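"""Run configuration: structured config files, overrides, and sidecars.

Config files are YAML or JSON mappings whose keys mirror the public
parameter names (``ObserverParams`` fields under ``params``, design
overrides under ``design``, grid settings under ``grid``, fit settings
under ``fit``).  Command-line flags override config values; every run
writes its fully resolved configuration next to its outputs so any run
is reproducible from the sidecar alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .observer_core import Grid, ObserverParams

__all__ = ["load_config", "merge_config", "save_sidecar", "params_from_config", "grid_from_config"]


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    elif path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:  # fall back to YAML, which is a JSON superset
        cfg = yaml.safe_load(text)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def merge_config(base: dict, overrides: dict) -> dict:
    """Recursive merge; override values win, None overrides are skipped."""
    out = dict(base)
    for k, v in overrides.items():
        if v is None:
            continue
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = merge_config(out[k], v)
        else:
            out[k] = v
    return out


def params_from_config(cfg: dict) -> ObserverParams:
    section = cfg.get("params", cfg)
    return ObserverParams.from_dict(section)


def grid_from_config(cfg: dict) -> Grid:
    section = cfg.get("grid", {})
    return Grid(
        half_span=float(section.get("half_span", 80.0)),
        step=float(section.get("step", 0.2)),
    )


def save_sidecar(cfg: dict, path) -> None:
    Path(path).write_text(json.dumps(cfg, indent=2, default=_jsonable))


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return str(obj)
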