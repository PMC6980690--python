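"""Per-object normalization of raw trace values.

Methods (``I`` is the raw value of one object, ``I0`` the mean of its
values inside the baseline window):

========== =======================================
``none``       identity
``fold``       I / I0
``delta_fold`` (I - I0) / I0
``div_max``    I / max(I)
``minmax``     (I - min(I)) / (max(I) - min(I))
========== =======================================

Normalization is computed per object within its condition; conditions
never share baselines.  The baseline window is an inclusive time
interval ``[t_lo, t_hi]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import TraceSet

__all__ = ["NormalizationSpec", "baseline_value", "apply_normalization", "METHODS"]

METHODS = ("none", "fold", "delta_fold", "div_max", "minmax")


@dataclass(frozen=True)
class NormalizationSpec:
    method: str = "none"
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"unknown normalization method {self.method!r}; "
                f"choose one of {METHODS}"
            )
        if self.method in ("fold", "delta_fold"):
            if self.baseline_window is None:
                raise ValueError(f"method {self.method!r} requires a baseline window")
            lo, hi = self.baseline_window
            if not lo <= hi:
                raise ValueError("baseline window must satisfy t_lo <= t_hi")


def baseline_value(trace_values_in_window) -> float:
    """I0: arithmetic mean of the non-missing values inside the window."""
    vals = np.asarray(trace_values_in_window, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("baseline window contains no values")
    return float(vals.mean())


def _normalize_one(obj: str, g: pd.DataFrame, spec: NormalizationSpec) -> pd.Series:
    v = g["value"].to_numpy(dtype=float)
    if spec.method == "none":
        return g["value"]
    if spec.method in ("fold", "delta_fold"):
        lo, hi = spec.baseline_window  # type: ignore[misc]
        in_win = (g["time"] >= lo) & (g["time"] <= hi)
        window_vals = v[in_win.to_numpy()]
        window_vals = window_vals[~np.isnan(window_vals)]
        if window_vals.size == 0:
            raise ValueError(
                f"object {obj!r}: no values in baseline window [{lo}, {hi}]"
            )
        i0 = baseline_value(window_vals)
        if i0 == 0:
            raise ValueError(f"object {obj!r}: baseline I0 is zero")
        out = v / i0 if spec.method == "fold" else (v - i0) / i0
    elif spec.method == "div_max":
        mx = np.nanmax(v) if not np.isnan(v).all() else np.nan
        if not np.isfinite(mx) or mx == 0:
            raise ValueError(f"object {obj!r}: maximum is zero or undefined")
        out = v / mx
    else:  # minmax
        if np.isnan(v).all():
            raise ValueError(f"object {obj!r}: all values missing")
        mx, mn = np.nanmax(v), np.nanmin(v)
        if mx == mn:
            raise ValueError(f"object {obj!r}: constant trace, min equals max")
        out = (v - mn) / (mx - mn)
    return pd.Series(out, index=g.index)


def apply_normalization(ts: TraceSet, spec: NormalizationSpec) -> TraceSet:
    """Return a new TraceSet with per-object normalized values.

    Times, ids and record order are unchanged; missing values stay missing.
    """
    if spec.method == "none":
        return ts.copy()
    df = ts.data.copy()
    for (cond, obj), g in df.groupby(["condition_id", "object_id"], sort=False):
        df.loc[g.index, "value"] = _normalize_one(obj, g, spec)
    return TraceSet(df)
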