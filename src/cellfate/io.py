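"""Tidy-file I/O: CSV tables, YAML configs, JSON results, run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .inference import validate_count_table

__all__ = [
    "load_count_table",
    "save_count_table",
    "load_config",
    "save_json",
    "write_manifest",
]


def load_count_table(path) -> pd.DataFrame:
    """Read and validate a tidy count-table CSV."""
    df = pd.read_csv(path)
    return validate_count_table(df)


def save_count_table(df: pd.DataFrame, path) -> None:
    validate_count_table(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def save_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_manifest(outdir, config: dict, seed: int) -> Path:
    """Record the run configuration next to its outputs for reproducibility."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    save_json({"config": config, "seed": seed, "version": __version__}, path)
    return path
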