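"""Run configuration: defaults, YAML overrides, stable hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

from .conversion import ConversionModel
from .errors import ConfigurationError
from .metrics import DEFAULT_REGION_F, RegionCoefficients

DEFAULTS: dict[str, Any] = {
    "regions": dict(DEFAULT_REGION_F),  # region -> f, mSv/(mGy*cm)
    "conversion": {
        "mode": "fit",  # "fit" | "table"
        "phantom": "body32",
        "table_path": None,  # site-supplied (phantom, deff_cm, k) CSV
        "clamp": True,  # clamp Deff to the validity range vs raise
    },
    "report": {
        "dose_decimals": 2,  # mGy / mSv rounding in rendered tables
        "percent_decimals": 0,
        "format": "csv",  # "csv" | "md"
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Defaults, optionally overridden by a YAML file (deep-merged)."""
    if path is None:
        return json.loads(json.dumps(DEFAULTS))
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return _merge(DEFAULTS, override)


def config_hash(config: dict[str, Any]) -> str:
    """Short stable digest of a configuration for run manifests."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def conversion_model_from_config(config: dict[str, Any]) -> ConversionModel:
    conv = config.get("conversion", {})
    phantom = conv.get("phantom", "body32")
    clamp = bool(conv.get("clamp", True))
    if conv.get("mode", "fit") == "table":
        return ConversionModel.aapm204_table(phantom, conv.get("table_path"), clamp=clamp)
    return ConversionModel.aapm204_fit(phantom, clamp=clamp)


def region_coefficients_from_config(config: dict[str, Any]) -> RegionCoefficients:
    return RegionCoefficients(f_by_region=dict(config.get("regions", DEFAULT_REGION_F)))
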