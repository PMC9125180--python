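import numpy as np
import pandas as pd
import pytest

from pawtrack import TrackingTable


def make_table(parts: dict[str, np.ndarray], fps: float = 30.0,
               likelihood: dict[str, np.ndarray] | None = None,
               units: str = "pixel") -> TrackingTable:
    """Build a TrackingTable from {part: (n, 2) xy array} (test helper)."""
    cols = {}
    for name, xy in parts.items():
        xy = np.asarray(xy, float)
        cols[(name, "x")] = xy[:, 0]
        cols[(name, "y")] = xy[:, 1]
        if likelihood is not None:
            cols[(name, "likelihood")] = np.asarray(likelihood[name], float)
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
    return TrackingTable(df, fps=fps, units=units)


@pytest.fixture
def two_part_table() -> TrackingTable:
    rng = np.random.default_rng(7)
    n = 100
    return make_table(
        {
            "snout": rng.uniform(0, 640, size=(n, 2)),
            "tail": rng.uniform(0, 640, size=(n, 2)),
        },
        likelihood={"snout": np.ones(n), "tail": np.ones(n)},
    )
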