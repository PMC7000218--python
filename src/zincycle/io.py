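"""File I/O: TIFF stacks, versioned CSV tables, and JSON sidecars.

All CSV outputs carry a ``# zincycle-schema: <name>/<version>`` header line;
readers reject unknown schema versions loudly so stale outputs cannot be
silently re-ingested.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

SCHEMA_VERSION = "1"


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (frames, H, W) stack as a multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_label_stack(path, stacks: list[np.ndarray]) -> None:
    """Write label masks as 16-bit multi-page TIFF."""
    arr = np.stack([np.asarray(s) for s in stacks]).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def write_table(path, df: pd.DataFrame, schema: str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# zincycle-schema: {schema}/{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        expect = f"# zincycle-schema: {schema}/{SCHEMA_VERSION}"
        if header != expect:
            raise ValueError(
                f"{path}: unexpected schema header {header!r}; expected {expect!r}"
            )
        return pd.read_csv(fh)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (frozenset, set)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, tuple):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
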