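import numpy as np
import pandas as pd
import pytest

import hurdleda as h


@pytest.fixture
def small_counts():
    """Tiny counts table with hand-checkable values."""
    return h.FeatureTable(pd.DataFrame(
        {"fA": [2, 1, 0, 4], "fB": [3, 1, 0, 0], "fC": [5, 2, 0, 6]},
        index=["s1", "s2", "s3", "s4"],
    ), scale="counts")


@pytest.fixture(scope="module")
def standard_dataset():
    """One default-condition simulated study, reused across tests."""
    return h.simulate_dataset(n=50, m=100, g=5, seed=11)


@pytest.fixture(scope="module")
def analyzed(standard_dataset):
    records = h.analyze_dataset(standard_dataset, seed=11)
    return standard_dataset, records


def dense_logsim(n=120, m=40, slope=0.0, seed=0, covariate=None, sd=1.0):
    """Dense (no zeros) log-normal relative-abundance data for tests.

    Returns (relative table, metadata) where every feature's log2
    absolute abundance is mu_i + slope_i * x + noise. ``slope`` may be
    scalar (applied to all features) or an array of per-feature slopes.
    """
    rng = np.random.default_rng(seed)
    x = covariate if covariate is not None else rng.standard_normal(n)
    mu = rng.uniform(-8, -2, m)
    slopes = np.broadcast_to(np.asarray(slope, dtype=float), (m,))
    log2A = mu[None, :] + np.outer(x, slopes) + rng.standard_normal((n, m)) * sd
    A = np.exp2(log2A)
    rel = A / A.sum(axis=1, keepdims=True)
    idx = [f"s{k}" for k in range(n)]
    table = h.FeatureTable(
        pd.DataFrame(rel, index=idx, columns=[f"f{i}" for i in range(m)]),
        scale="relative")
    metadata = pd.DataFrame({"x": x}, index=idx)
    return table, metadata
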