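"""Configuration loading, result serialization and run manifests.

Configuration is YAML: a ``condition`` (nsr/caf), optional ``iso_um``,
multiplicative ``gsk_scale`` / ``kd_scale``, a free-form ``overrides``
mapping of parameter fields, and protocol settings. Unknown keys are
rejected. Results round-trip through CSV (tables) and JSON (thresholds,
manifests) at full double precision.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .parameters import (PARAM_NAMES, ModelParameters, apply_caf, apply_iso,
                         nsr_parameters)
from .protocols import ThresholdResult

_TOP_KEYS = {"condition", "iso_um", "gsk_scale", "kd_scale", "sk_remodeling",
             "overrides", "protocol"}


class ConfigError(ValueError):
    pass


def build_parameters(condition: str = "nsr", iso_um: float = 0.0,
                     gsk_scale: float = 1.0, kd_scale: float = 1.0,
                     sk_remodeling: bool = False,
                     overrides: dict | None = None) -> ModelParameters:
    """Resolve a parameter set from condition flags and overrides."""
    bad = set(overrides or {}) - set(PARAM_NAMES)
    if bad:
        raise ConfigError(f"unknown parameter override(s): {sorted(bad)}")
    params = nsr_parameters(**(overrides or {}))
    if condition == "caf":
        params = apply_caf(params, sk_remodeling=sk_remodeling)
    elif condition != "nsr":
        raise ConfigError(f"unknown condition {condition!r} (nsr|caf)")
    if iso_um:
        params = apply_iso(params, iso_um)
    if gsk_scale != 1.0:
        params = params.scaled(g_sk=gsk_scale)
    if kd_scale != 1.0:
        params = params.scaled(kd_sk=kd_scale)
    return params


def load_config(path) -> tuple[ModelParameters, dict]:
    """Load a YAML run configuration -> (parameters, protocol settings)."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    protocol = cfg.get("protocol") or {}
    if not isinstance(protocol, dict):
        raise ConfigError(f"{path}: 'protocol' must be a mapping")
    params = build_parameters(
        condition=cfg.get("condition", "nsr"),
        iso_um=float(cfg.get("iso_um", 0.0)),
        gsk_scale=float(cfg.get("gsk_scale", 1.0)),
        kd_scale=float(cfg.get("kd_scale", 1.0)),
        sk_remodeling=bool(cfg.get("sk_remodeling", False)),
        overrides=cfg.get("overrides"))
    return params, protocol


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_threshold(result: ThresholdResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=1)


def read_threshold(path) -> ThresholdResult:
    with open(path) as fh:
        d = json.load(fh)
    import math
    return ThresholdResult(
        value=math.nan if d["value"] is None else float(d["value"]),
        resolution=float(d["resolution"]), detected=bool(d["detected"]),
        units=d["units"], trials=[(float(v), bool(o)) for v, o in d["trials"]])


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_trace_csv(trace, path) -> None:
    trace.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def run_manifest(params: ModelParameters, protocol: str, seed: int | None,
                 settings: dict | None = None) -> dict:
    return {
        "package_version": __version__,
        "python": platform.python_version(),
        "protocol": protocol,
        "seed": seed,
        "parameters_hash": params.content_hash(),
        "condition": params.condition,
        "iso_um": params.iso_concentration,
        "settings": settings or {},
    }


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
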