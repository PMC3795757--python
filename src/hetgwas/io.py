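"""Result-table I/O and run configuration.

All command outputs are tab-separated tables with a single ``# params:``
provenance comment (JSON, including the seed) ahead of the header so a run
can be reproduced from its output file alone.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = ["write_results", "read_results", "load_config", "merge_config"]


def write_results(table: pd.DataFrame, path, params: Mapping) -> None:
    """Write a TSV with a ``# params:`` provenance line; lossless re-read."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# params: " + json.dumps(dict(params), sort_keys=True) + "\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_results(path):
    """Read a results TSV; returns (DataFrame, params dict)."""
    path = Path(path)
    text = path.read_text()
    params: dict = {}
    lines = text.splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# params:"):
            params = json.loads(line.split(":", 1)[1])
            body_start = i + 1
        elif not line.startswith("#"):
            break
    table = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t")
    return table, params


def load_config(path) -> dict:
    """Load a YAML or JSON config file into a flat mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return cfg


def merge_config(file_cfg: Mapping, flag_cfg: Mapping, allowed) -> dict:
    """Flags override file values; unknown file keys are rejected by name."""
    allowed = set(allowed)
    unknown = set(file_cfg) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = dict(file_cfg)
    for key, value in flag_cfg.items():
        if value is not None:
            merged[key] = value
    return merged
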