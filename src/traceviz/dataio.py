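"""Reading, converting and writing trace tables.

Two input layouts are supported:

* **wide** — spreadsheet style: the first column holds the time points and
  every other column is one measured object.  One file per condition; the
  file name labels the condition.
* **tidy** — long format: one row per observation, with user-designated
  time / value / object / condition columns.

Everything is converted to the canonical tidy :class:`TraceSet`, the
universal in-memory representation used by every other module.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraceSet",
    "ColumnMapping",
    "sanitize_header",
    "read_wide",
    "read_wide_multi",
    "read_tidy",
    "deselect",
    "write_tidy",
]

#: fixed column order of the canonical tidy table
TIDY_COLUMNS = ("time", "value", "object_id", "condition_id")


@dataclass
class TraceSet:
    """Tidy table of (time, value, object id, condition id) records.

    ``data`` is a :class:`pandas.DataFrame` with exactly the columns
    ``time`` (float), ``value`` (float, NaN = missing), ``object_id`` (str)
    and ``condition_id`` (str).  Within a condition, (object_id, time)
    pairs are unique.  Construction validates and normalizes dtypes.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in TIDY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"TraceSet is missing column(s): {missing}")
        df = df.loc[:, list(TIDY_COLUMNS)].reset_index(drop=True)
        df["time"] = pd.to_numeric(df["time"], errors="raise").astype(float)
        df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)
        df["object_id"] = df["object_id"].astype(str)
        df["condition_id"] = df["condition_id"].astype(str)
        if df["time"].isna().any() or np.isinf(df["time"]).any():
            raise ValueError("time entries must be finite")
        if np.isinf(df["value"]).any():
            raise ValueError("value entries must be finite or missing (NaN)")
        if (df["object_id"].str.len() == 0).any():
            raise ValueError("object ids must be non-empty")
        dup = df.duplicated(subset=["condition_id", "object_id", "time"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise ValueError(
                "duplicate (object, time) pair within a condition: "
                f"object {row['object_id']!r} at time {row['time']} "
                f"in condition {row['condition_id']!r}"
            )
        self.data = df

    # -- introspection -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def objects(self) -> list[str]:
        """Object ids in order of first appearance."""
        return list(dict.fromkeys(self.data["object_id"]))

    def conditions(self) -> list[str]:
        """Condition ids in order of first appearance."""
        return list(dict.fromkeys(self.data["condition_id"]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraceSet):
            return NotImplemented
        return self.data.equals(other.data)

    def copy(self) -> "TraceSet":
        return TraceSet(self.data.copy())


@dataclass(frozen=True)
class ColumnMapping:
    """Designates which tidy-input columns hold what."""

    time_col: str
    value_col: str
    object_col: str
    condition_col: str | None = None

    def __post_init__(self) -> None:
        names = [self.time_col, self.value_col, self.object_col]
        if self.condition_col is not None:
            names.append(self.condition_col)
        if len(set(names)) != len(names):
            raise ValueError("mapped columns must be distinct")


def sanitize_header(names: Sequence[str]) -> list[str]:
    """Replace spaces in column names with underscores; dedupe with suffixes.

    Duplicates after replacement get a numeric suffix (``_2``, ``_3``, ...).
    Idempotent: applying twice gives the same result.
    """
    if len(names) == 0:
        raise ValueError("header must contain at least one column name")
    out: list[str] = []
    seen: dict[str, int] = {}
    for i, raw in enumerate(names):
        name = "" if raw is None else str(raw)
        if name.strip() == "":
            raise ValueError(f"empty column name at index {i}")
        name = name.replace(" ", "_")
        if name in seen:
            k = seen[name] + 1
            while f"{name}_{k}" in seen:
                k += 1
            seen[name] = k
            name = f"{name}_{k}"
        seen.setdefault(name, 1)
        out.append(name)
    return out


def _read_table(source: str | os.PathLike | IO) -> pd.DataFrame:
    """Read a CSV or XLSX table as strings (first sheet for XLSX)."""
    path = str(source) if isinstance(source, (str, os.PathLike)) else ""
    if path.lower().endswith((".xlsx", ".xls")):
        df = pd.read_excel(source, sheet_name=0, dtype=str)
    else:
        df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    if df.shape[1] < 1:
        raise ValueError("input table has no columns")
    return df


def _parse_float(x) -> float:
    # python's float() is correctly rounded; pandas' fast parser is not
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return np.nan
    try:
        return float(x)
    except (TypeError, ValueError):
        return np.nan


def _numeric_column(col: pd.Series, name: str, strict: bool) -> pd.Series:
    converted = col.map(_parse_float)
    bad = converted.isna() & col.notna()
    if bad.any():
        # +2: one for the header line, one for 0-based indexing
        row = int(bad.idxmax()) + 2
        if strict:
            raise ValueError(
                f"non-numeric entry {col[bad.idxmax()]!r} in column "
                f"{name!r} at row {row}"
            )
        warnings.warn(
            f"non-numeric entry in column {name!r} at row {row} "
            "treated as missing",
            stacklevel=3,
        )
    return converted.astype(float)


def read_wide(source: str | os.PathLike | IO, condition_label: str = "1") -> TraceSet:
    """Read a wide table: first column = time, one column per object.

    Emits one record per (time row, object column) — exactly
    ``n_times * n_objects`` records; empty cells become missing values.
    """
    df = _read_table(source)
    if df.shape[1] < 2:
        raise ValueError(
            "wide input needs a time column plus at least one object column"
        )
    if df.shape[0] < 1:
        raise ValueError("wide input has no data rows")
    header = sanitize_header(list(df.columns))
    df.columns = header
    time = _numeric_column(df.iloc[:, 0], header[0], strict=True)
    frames = []
    for obj in header[1:]:
        values = _numeric_column(df[obj], obj, strict=True)
        frames.append(
            pd.DataFrame(
                {
                    "time": time.to_numpy(),
                    "value": values.to_numpy(),
                    "object_id": obj,
                    "condition_id": condition_label,
                }
            )
        )
    return TraceSet(pd.concat(frames, ignore_index=True))


def _condition_label(name: str) -> str:
    base = os.path.basename(str(name))
    return os.path.splitext(base)[0]


def read_wide_multi(
    files: Iterable[str | os.PathLike | tuple[str, IO]],
) -> TraceSet:
    """Read several wide files; each file becomes one condition.

    The condition label is the file basename without extension.  Object ids
    colliding across files are disambiguated by prefixing the condition
    (``cond:object``).
    """
    entries: list[tuple[str, object]] = []
    for f in files:
        if isinstance(f, tuple):
            entries.append((str(f[0]), f[1]))
        else:
            entries.append((str(f), f))
    if not entries:
        raise ValueError("at least one file is required")
    labels = [_condition_label(name) for name, _ in entries]
    dup = {x for x in labels if labels.count(x) > 1}
    if dup:
        raise ValueError(f"duplicate file name(s): {sorted(dup)}")

    parts = [read_wide(src, condition_label=lab) for (_, src), lab in zip(entries, labels)]
    seen: dict[str, int] = {}
    for part in parts:
        for obj in part.objects():
            seen[obj] = seen.get(obj, 0) + 1
    colliding = {o for o, n in seen.items() if n > 1}
    if colliding:
        for part in parts:
            df = part.data
            mask = df["object_id"].isin(colliding)
            df.loc[mask, "object_id"] = (
                df.loc[mask, "condition_id"] + ":" + df.loc[mask, "object_id"]
            )
    return TraceSet(pd.concat([p.data for p in parts], ignore_index=True))


def read_tidy(source: str | os.PathLike | IO, mapping: ColumnMapping) -> TraceSet:
    """Read a tidy table using an explicit column mapping.

    When no condition column is mapped the condition defaults to ``"1"``.
    """
    df = _read_table(source)
    wanted = [mapping.time_col, mapping.value_col, mapping.object_col]
    if mapping.condition_col is not None:
        wanted.append(mapping.condition_col)
    for col in wanted:
        if col not in df.columns:
            raise ValueError(f"mapped column {col!r} not found in input header")
    out = pd.DataFrame(
        {
            "time": _numeric_column(df[mapping.time_col], mapping.time_col, strict=True),
            "value": _numeric_column(df[mapping.value_col], mapping.value_col, strict=True),
            "object_id": df[mapping.object_col].astype(str),
            "condition_id": (
                df[mapping.condition_col].astype(str)
                if mapping.condition_col is not None
                else "1"
            ),
        }
    )
    return TraceSet(out)


def deselect(ts: TraceSet, object_ids: Iterable[str]) -> TraceSet:
    """Drop the named objects.  Unknown ids are ignored with a warning."""
    wanted = {str(o) for o in object_ids}
    present = set(ts.objects())
    unknown = sorted(wanted - present)
    if unknown:
        warnings.warn(
            f"deselect: object id(s) not present: {unknown}", stacklevel=2
        )
    keep = ~ts.data["object_id"].isin(wanted)
    return TraceSet(ts.data.loc[keep].reset_index(drop=True))


def write_tidy(ts: TraceSet, sink: str | os.PathLike | IO) -> None:
    """Write the canonical tidy CSV (``time,value,object_id,condition_id``).

    Missing values are written as empty fields and survive a round-trip
    through :func:`read_tidy`.
    """
    # %.17g round-trips IEEE doubles exactly
    ts.data.to_csv(
        sink, index=False, columns=list(TIDY_COLUMNS), na_rep="",
        float_format="%.17g",
    )


#: mapping that reads back files produced by :func:`write_tidy`
TIDY_MAPPING = ColumnMapping(
    time_col="time",
    value_col="value",
    object_col="object_id",
    condition_col="condition_id",
)
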