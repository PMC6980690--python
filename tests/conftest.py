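import io

import matplotlib
import pandas as pd
import pytest

matplotlib.use("Agg")

from traceviz.dataio import TraceSet
from traceviz.simulate import FixtureSpec, generate_traces


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    import matplotlib.pyplot as plt

    plt.close("all")


@pytest.fixture
def small_ts() -> TraceSet:
    """3 objects x 4 times, one condition, hand-enterable values."""
    rows = []
    for obj, vals in {"A": [2, 2, 4, 8], "B": [1, 2, 3, 4], "C": [5, 5, 5, 5]}.items():
        for t, v in zip([0, 1, 2, 3], vals):
            rows.append((float(t), float(v), obj, "1"))
    return TraceSet(pd.DataFrame(rows, columns=["time", "value", "object_id", "condition_id"]))


@pytest.fixture
def sim_ts() -> TraceSet:
    return generate_traces(FixtureSpec(n_objects=6, seed=7))


def wide_csv(text: str) -> io.StringIO:
    return io.StringIO(text)
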