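"""Reading and writing count matrices and run reports.

Count matrices travel as delimited text (TSV/CSV autodetected from the
extension) with a header row of feature names and identifiers in the
first column.  Counts stay exact integers end to end — nothing is
silently coerced to float — because the integer lattice is the point of
the analysis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["read_count_matrix", "write_count_matrix", "write_report"]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_count_matrix(path, orientation: str = "samples_by_features") -> pd.DataFrame:
    """Read an integer count matrix, normalized to samples x features.

    The file must have a header row and row identifiers in the first
    column.  Non-integer or negative cells raise with the offending
    row/column named.  ``orientation='features_by_samples'`` transposes
    the input.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    for col in df.columns:
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError(f"non-numeric cell in column {col!r}")
        if np.any(vals != np.floor(vals)):
            i = df.index[np.nonzero(vals != np.floor(vals))[0][0]]
            raise ValueError(f"non-integer count at row {i!r}, column {col!r}")
        if np.any(vals < 0):
            i = df.index[np.nonzero(vals < 0)[0][0]]
            raise ValueError(f"negative count at row {i!r}, column {col!r}")
    df = df.astype(np.int64)
    if orientation == "features_by_samples":
        df = df.T
    return df


def write_count_matrix(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep(path))


def write_report(result: dict, path, fmt: str = "json", config: dict | None = None) -> None:
    """Write a result dictionary with provenance (version + config echoed).

    JSON output has deterministic key order, so identical inputs and
    configuration produce byte-identical reports.  NaN values are
    serialized as null.
    """
    payload = {
        "package": "latticecoda",
        "version": __version__,
        "config": dict(sorted((config or {}).items())),
        "result": result,
    }
    path = Path(path)
    if fmt == "json":
        text = json.dumps(_jsonable(payload), indent=2, sort_keys=True)
        path.write_text(text + "\n")
    elif fmt == "tsv":
        pd.DataFrame(result).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if f != f else f
    return obj
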