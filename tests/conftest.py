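import numpy as np
import pandas as pd
import pytest

from cellfate import RateParams, StateVector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def generic_params():
    return RateParams(alpha=0.6, beta=0.2, gamma=0.1, d1=0.08, d2=0.15)


@pytest.fixture
def generic_init():
    return StateVector(P=30.0, D=2.0, N=1.0)


def make_count_table(pred, days=None, n_fields=1, jitter=None, rng=None):
    """Tidy count table whose per-field counts equal ``pred`` (n_days, 3),
    optionally plus noise drawn with ``rng``."""
    pred = np.asarray(pred, dtype=float)
    days = np.arange(pred.shape[0]) if days is None else np.asarray(days)
    rows = []
    for i, day in enumerate(days):
        for j, state in enumerate(("P", "D", "N")):
            for f in range(n_fields):
                val = pred[i, j]
                if jitter is not None:
                    val += rng.normal(0.0, jitter)
                rows.append((day, state, val, f + 1))
    return pd.DataFrame(rows, columns=["day", "state", "count", "field_id"])


@pytest.fixture
def count_table_factory():
    return make_count_table
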