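"""Per-condition mean and 95% confidence-interval curves.

The CI of the mean at each time point is the classic small-sample
t-interval, ``mean +/- t(0.975, n-1) * sd / sqrt(n)``.  Overlap (or
lack of it) between the ribbons of two conditions supports "visual
inference" about differences between them.  With a single object
(n = 1) the interval is undefined and reported as NaN.

Times are grouped by exact numeric equality; no interpolation is done
across unequal grids, so per-time n may vary when grids differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import TraceSet

__all__ = ["SummaryCurve", "summarize", "CONFIDENCE_LEVEL"]

CONFIDENCE_LEVEL = 0.95


@dataclass
class SummaryCurve:
    """Mean/CI curve for one condition.

    ``points`` has columns ``time``, ``mean``, ``ci_lo``, ``ci_hi``, ``n``,
    sorted by time; ``ci_lo``/``ci_hi`` are NaN where n = 1.
    """

    condition_id: str
    points: pd.DataFrame = field(repr=False)


def summarize(ts: TraceSet, level: float = CONFIDENCE_LEVEL) -> list[SummaryCurve]:
    """Mean and CI over objects, per condition and time point."""
    curves: list[SummaryCurve] = []
    for cond in ts.conditions():
        sub = ts.data[ts.data["condition_id"] == cond]
        rows = []
        for t, g in sub.groupby("time", sort=True):
            vals = g["value"].dropna().to_numpy(dtype=float)
            n = vals.size
            if n == 0:
                continue
            mean = float(vals.mean())
            if n >= 2:
                sd = float(vals.std(ddof=1))
                half = stats.t.ppf(0.5 + level / 2, n - 1) * sd / np.sqrt(n)
                lo, hi = mean - half, mean + half
            else:
                lo = hi = np.nan
            rows.append((float(t), mean, lo, hi, n))
        points = pd.DataFrame(
            rows, columns=["time", "mean", "ci_lo", "ci_hi", "n"]
        )
        curves.append(SummaryCurve(condition_id=cond, points=points))
    return curves
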