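import numpy as np
import pandas as pd
import pytest

from fallowcast import RunConfig, generate_et_series, generate_landscape
from fallowcast.synthetic_landscape import pixel_month_table


def small_search_space():
    return {"max_iter": [100, 200], "learning_rate": [0.1], "max_depth": [None, 4]}


@pytest.fixture(scope="session")
def small_config():
    return RunConfig(
        n_rows=60,
        n_cols=60,
        fallow_fraction=0.2,
        n_search_candidates=2,
        search_subsample=5000,
        search_space=small_search_space(),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_series(small_truth):
    return generate_et_series(small_truth)


@pytest.fixture(scope="session")
def small_pixels(small_truth, small_series):
    return pixel_month_table(small_truth, small_series, include_natural=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_annual(et_ag, **cols):
    """Minimal annual-pixel frame for statistics and scenario tests."""
    n = len(et_ag)
    base = {
        "pixel_id": np.arange(n),
        "year": np.full(n, 2019),
        "x": np.arange(n, dtype=float) * 70.0,
        "y": np.zeros(n),
        "et_ag_mm": np.asarray(et_ag, dtype=float),
    }
    base.update(cols)
    return pd.DataFrame(base)
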