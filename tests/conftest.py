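import numpy as np
import pandas as pd
import pytest

from intercrop_eval.simulate import TraitSpec, TrialDesign
from intercrop_eval.topsis import DecisionMatrix, Indicator


def make_matrix(rows, directions=None, weights=None, intervals=None, labels=None):
    """Build a DecisionMatrix from a nested list."""
    rows = np.asarray(rows, dtype=float)
    n, m = rows.shape
    directions = directions or ["benefit"] * m
    weights = weights or [1.0] * m
    intervals = intervals or {}
    inds = []
    for j in range(m):
        lo, hi = intervals.get(j, (None, None))
        inds.append(Indicator(f"c{j}", directions[j], weight=weights[j],
                              interval_low=lo, interval_high=hi))
    labels = labels or [f"t{i}" for i in range(n)]
    return DecisionMatrix(pd.DataFrame(rows, index=labels, columns=[i.name for i in inds]), inds)


def random_matrix(rng, max_dim=5, allow_interval=False):
    """Random small decision matrix with mixed directions and weights."""
    n = rng.integers(2, max_dim + 1)
    m = rng.integers(1, max_dim + 1)
    rows = rng.uniform(0.5, 10.0, size=(n, m))
    directions = [str(rng.choice(["benefit", "cost"])) for _ in range(m)]
    intervals = {}
    if allow_interval and m >= 2 and rng.random() < 0.5:
        j = int(rng.integers(0, m))
        directions[j] = "interval"
        intervals[j] = (4.0, 6.0)
    weights = rng.uniform(0.1, 2.0, size=m).tolist()
    return make_matrix(rows, directions, weights, intervals), rows, directions, weights, intervals


@pytest.fixture
def small_null_design():
    """No-effect design: one region, two intercrops, three traits, n=10."""
    traits = tuple(
        TraitSpec(name, control_mean=50.0, cv=0.2, effects={})
        for name in ("trait_a", "trait_b", "trait_c")
    )
    return TrialDesign(
        regions={"R": ("T1", "T2", "ctrl")},
        controls={"R": "ctrl"},
        traits=traits,
        n_agronomic=10,
        n_soil=4,
    )
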