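"""YAML run configuration: schema, validation, and seed fan-out.

Unknown keys are rejected (typos in a config should fail loudly, not be
silently ignored)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

STAGES = (
    "simulate",
    "preprocess",
    "cluster",
    "tissue-pref",
    "score",
    "trajectory",
    "grn",
    "activity",
    "rank",
)

SCHEMA: dict[str, Any] = {
    "seed": int,
    "outdir": str,
    "stages": list,
    "input": {
        "counts": str,
        "format": str,
        "annotation": str,
        "gmt": str,
        "tf_list": str,
        "regulons": list,
    },
    "simulate": {
        "n_genes": int, "n_tfs": int, "regulon_size": int, "frac_repressed": float,
        "n_cells": int, "n_patients": int, "n_tissues": int,
        "effect_strength": float, "nb_dispersion": float, "library_size_mean": float,
        "tf_self_expression": bool, "trunk_persists": bool, "seed": int,
    },
    "preprocess": {"min_cells_per_gene": int, "min_genes_per_cell": int},
    "grn": {
        "n_bins": int, "n_boot": int, "support_frac": float,
        "min_regulon_size": int, "tolerance": float, "n_perm": int,
        "branch_min_cells": int,
    },
    "cluster": {"n_pcs": int, "k": int, "resolution": float, "on": str},
    "rank": {"q_max": float, "min_size": int, "top_k": int, "min_overlap": int},
}


class ConfigError(ValueError):
    pass


def validate_config(cfg: dict) -> dict:
    """Reject unknown keys anywhere in the config tree; return cfg."""
    _validate_block(cfg, SCHEMA, path="")
    for stage in cfg.get("stages", []):
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}; valid: {', '.join(STAGES)}")
    return cfg


def _validate_block(block: dict, schema: dict, path: str) -> None:
    if not isinstance(block, dict):
        raise ConfigError(f"config section {path or '<root>'} must be a mapping")
    for key, value in block.items():
        where = f"{path}.{key}" if path else key
        if key not in schema:
            raise ConfigError(f"unknown config key {where!r}")
        expected = schema[key]
        if isinstance(expected, dict):
            _validate_block(value, expected, where)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
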