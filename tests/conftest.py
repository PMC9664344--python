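import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import airwaycomp as aw


def brute_force_two_sided_p(x, y):
    """Independent oracle: enumerate every assignment of the pooled values.

    For tie-free inputs, the two-sided p is 2 * min(P(U <= u), P(U >= u))
    over all C(n1+n2, n1) relabelings, capped at 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            for idx in itertools.combinations(range(len(pooled)), n1)
        ]
    )
    cdf = (us <= u_obs + 1e-9).mean()
    sf = (us >= u_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(cdf, sf))


@pytest.fixture(scope="session")
def two_type_profiles():
    """Two cell types over 30 genes: 5 target-only markers, shared rest."""
    genes = [f"g{i:02d}" for i in range(30)]
    w_t = pd.Series(0.0, index=genes)
    w_t[genes[:5]] = 0.1
    w_t[genes[10:]] = 0.5 / 20
    w_b = pd.Series(0.0, index=genes)
    w_b[genes[5:10]] = 0.1
    w_b[genes[10:]] = 0.5 / 20
    return [
        aw.CellTypeProfile.from_weights("target", w_t),
        aw.CellTypeProfile.from_weights("background", w_b),
    ]


@pytest.fixture(scope="session")
def small_scenario():
    """3 cohorts x 40 samples, 8-marker block, 40 decoys (fast variant)."""
    return aw.make_marker_discovery_scenario(
        n_cohorts=3, n_samples=40, n_markers=8, n_decoys=40, seed=11
    )


@pytest.fixture
def simple_counts():
    counts = pd.DataFrame(
        {"s1": [10, 20, 30, 0], "s2": [20, 40, 60, 0], "s3": [10, 20, 30, 0]},
        index=["g1", "g2", "g3", "gz"],
    )
    return aw.CountMatrix(counts)
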