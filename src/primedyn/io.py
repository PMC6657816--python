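"""Tabular writers and run manifests."""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .params import ModelParameters

__all__ = ["write_table", "read_table", "write_manifest"]

_SEPARATORS = {"csv": ",", "tsv": "\t"}


def write_table(records: pd.DataFrame, path: str | Path, format: str = "csv") -> Path:
    """Write a long-format delimited table with header, deterministic order.

    Numeric formatting is locale-independent (pandas repr); an empty frame
    yields a header-only file.
    """
    if format not in _SEPARATORS:
        raise ValueError(f"format must be one of {sorted(_SEPARATORS)}, got {format!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep=_SEPARATORS[format], index=False, lineterminator="\n")
    return path


def read_table(path: str | Path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix == ".tsv" else "csv"
    return pd.read_csv(path, sep=_SEPARATORS[format])


def write_manifest(
    path: str | Path,
    params: ModelParameters,
    command: str,
    seed: int | None = None,
    extra: Mapping[str, Any] | None = None,
) -> Path:
    """Emit a JSON run manifest (parameters + seed + package version)."""
    from . import __version__

    payload: dict[str, Any] = {
        "command": command,
        "package": "primedyn",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "parameters": params.to_dict(),
        "parameter_hash": params.hash(),
    }
    if extra:
        payload["extra"] = dict(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
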