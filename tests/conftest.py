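import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from markcorr.geometry import MarkedPattern


def make_pattern(xy, cids, windows, marks=None, dbh=None, ids=None):
    """Assemble a MarkedPattern from raw arrays (test helper)."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    trees = pd.DataFrame(
        {
            "tree_id": ids if ids is not None else [f"T{i:04d}" for i in range(n)],
            "concession_id": cids if not np.isscalar(cids) else [cids] * n,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "dbh_cm": dbh if dbh is not None else np.nan,
            "seed_kg": marks if marks is not None else 1.0,
            "agb_kg": np.nan,
        }
    )
    return MarkedPattern(trees, windows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform_pattern(rng):
    """200 uniform points with random marks in a 1 km square concession."""
    xy = rng.uniform(0, 1000, (200, 2))
    marks = rng.lognormal(3.0, 0.8, 200)
    return make_pattern(xy, "A", {"A": box(0, 0, 1000, 1000)}, marks=marks)


@pytest.fixture
def two_concession_pattern(rng):
    """Two adjacent concessions with interleaved points near the shared edge."""
    xy_a = rng.uniform([0, 0], [500, 500], (60, 2))
    xy_b = rng.uniform([500, 0], [1000, 500], (60, 2))
    xy = np.vstack([xy_a, xy_b])
    cids = ["A"] * 60 + ["B"] * 60
    windows = {"A": box(0, 0, 500, 500), "B": box(500, 0, 1000, 500)}
    marks = rng.lognormal(3.0, 0.5, 120)
    return make_pattern(xy, cids, windows, marks=marks)
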