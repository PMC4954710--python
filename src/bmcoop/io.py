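"""Reading and writing the round-record CSV schema and analysis outputs.

Round records are exchanged as RFC-4180 CSV (UTF-8, header mandatory) with
the columns of :data:`bmcoop.engine.RECORD_COLUMNS`; ``f_C_prev`` is empty
in round 1.  Externally collected data in the same schema (e.g. experiment
round logs) can be fed through the same analysis path.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .engine import RECORD_COLUMNS

__all__ = [
    "write_records",
    "read_records",
    "write_fits",
    "write_curves",
    "write_signature",
    "write_sweep",
]

PathLike = Union[str, Path]


def write_records(records: pd.DataFrame, path: PathLike) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing columns: {missing}")
    records.to_csv(path, index=False, columns=RECORD_COLUMNS)


class SchemaError(ValueError):
    """Raised when a records file violates the round-record schema."""


def _bad_rows(mask: pd.Series, what: str) -> str:
    rows = (np.flatnonzero(mask.to_numpy()) + 2)[:10]  # 1-based + header line
    return f"{what} (file rows {', '.join(map(str, rows))})"


def read_records(path: PathLike) -> pd.DataFrame:
    """Read and validate a round-record CSV; errors cite file row numbers."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    problems = []
    for col in ("run_id", "t", "player_id"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < (1 if col == "t" else 0)) | (vals % 1 != 0)
        if bad.any():
            problems.append(_bad_rows(bad, f"invalid {col}"))
        df[col] = vals.astype("Int64")
    bad_role = ~df["role"].isin(["learner", "defector"])
    if bad_role.any():
        problems.append(_bad_rows(bad_role, "role must be 'learner' or 'defector'"))
    fc = pd.to_numeric(df["f_C_prev"], errors="coerce")
    need_fc = (df["t"] >= 2) & fc.isna()
    if need_fc.any():
        problems.append(_bad_rows(need_fc, "f_C_prev required for t >= 2"))
    df["f_C_prev"] = fc
    for col in ("intended_p", "payoff"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["realized_ptilde"] = pd.to_numeric(df["realized_ptilde"], errors="coerce")
    if problems:
        raise SchemaError("; ".join(problems))
    return df[RECORD_COLUMNS]


def write_fits(fits, path: PathLike) -> None:
    pd.DataFrame([f.to_dict() for f in fits.values()] if isinstance(fits, dict)
                 else [f.to_dict() for f in fits]).to_csv(path, index=False)


def write_curves(curves, path: PathLike) -> None:
    frames = [c.to_frame() for c in (curves.values() if isinstance(curves, dict) else curves)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_signature(signature: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(signature, indent=2, default=_jsonable) + "\n")


def write_sweep(sweep_result, path: PathLike) -> None:
    sweep_result.table.to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
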