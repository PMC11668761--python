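"""Structured run configuration with validated, study-faithful defaults.

The default configuration encodes the pipeline's canonical settings: the
locality-fraction sweep {global, 3/4, 1/2, 1/8, 1/16, 1/64, 1/128}, 90 %
variance retention, an 80/20 train/test split, QC cut-offs (MAF 0.05, geno
0.1, mind 0.1, HWE exact p 0.001, snps-only), loading selection thresholds
0.2 with 0.15 fallback, covariate adjustment for sex, age and the first 10
genetic principal components, and a genome-wide significance line of 1e-8.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from pathlib import Path

import yaml

from .exceptions import ValidationError

__all__ = ["SCHEMA_VERSION", "default_config", "load_config", "parse_fraction", "config_hash"]

SCHEMA_VERSION = 1

_DEFAULTS: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "paths": {
        "fields_dir": None,
        "mask": None,
        "plink_prefix": None,
        "covariates": None,
        "label_atlas": None,
        "label_names": None,
        "output_dir": None,
    },
    "locpca": {
        "fractions": ["global", 0.75, 0.5, 0.125, 0.0625, 0.015625, 0.0078125],
        "variance_target": 0.9,
        "train_fraction": 0.8,
        "truncation_sigma_mult": 3.0,
    },
    "qc": {
        "maf_min": 0.05,
        "geno_max": 0.1,
        "mind_max": 0.1,
        "hwe_p_min": 0.001,
        "snps_only": True,
    },
    "gwas": {
        "significance_line": 1.0e-8,
        "loading_threshold": 0.2,
        "loading_fallback": 0.15,
        "n_genetic_pcs": 10,
        "covariates": ["sex", "age"],
    },
    "interpret": {
        "alphas": [-3, -2, -1, 0, 1, 2, 3],
        "stat": "mean",
    },
    "simulate": {},   # SimConfig overrides, validated against its fields
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def parse_fraction(value) -> float:
    """Map a config fraction entry to a float; 'global' means infinity."""
    if isinstance(value, str):
        if value.lower() in ("global", "inf", "infinity"):
            return math.inf
        try:
            value = float(value)
        except ValueError:
            raise ValidationError(f"unknown locality fraction {value!r}") from None
    v = float(value)
    if v <= 0:
        raise ValidationError(f"locality fraction must be > 0, got {v}")
    return v


def _check_keys(cfg: dict, allowed: dict, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in allowed:
            raise ValidationError(f"unknown config key {path + key!r}")
        if isinstance(allowed[key], dict) and key != "simulate":
            if not isinstance(val, dict):
                raise ValidationError(f"config key {path + key!r} must be a mapping")
            _check_keys(val, allowed[key], path=f"{path}{key}.")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config, validate against the schema, merge over defaults."""
    cfg = default_config()
    user: dict = {}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValidationError(f"{path}: config root must be a mapping")
    if overrides:
        user = _deep_merge(user, overrides)
    if "schema_version" in user and user["schema_version"] != SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported schema_version {user['schema_version']} "
            f"(expected {SCHEMA_VERSION})"
        )
    _check_keys(user, _DEFAULTS)
    if "simulate" in user and user["simulate"]:
        from .synthdata import SimConfig

        allowed = set(SimConfig.__dataclass_fields__)
        unknown = set(user["simulate"]) - allowed
        if unknown:
            raise ValidationError(f"unknown simulate keys: {sorted(unknown)}")
    cfg = _deep_merge(cfg, user)
    for f in cfg["locpca"]["fractions"]:
        parse_fraction(f)
    return cfg


def _deep_merge(base: dict, over: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def config_hash(cfg: dict) -> str:
    """Stable hash of a config for provenance records."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
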