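import numpy as np
import pandas as pd
import pytest

from regrowth.inventory import PLOT_COLUMNS
from regrowth.synthetic import single_type_config
from regrowth import generate_dataset


def make_plot_table(
    n=10,
    seed=0,
    forest_type="typeA",
    period="current",
    disturbed=None,
    **overrides,
):
    """Small hand-buildable plot table with valid invariants."""
    rng = np.random.default_rng(seed)
    years = {"past": (1990, 1999), "current": (2000, 2016)}[period]
    df = pd.DataFrame(
        {
            "plot_id": [f"p{i:04d}" for i in range(n)],
            "source": "SYNTH",
            "forest_type": forest_type,
            "lon": rng.uniform(-120, -70, n),
            "lat": rng.uniform(30, 55, n),
            "stand_age": rng.uniform(5, 300, n),
            "agb": rng.uniform(0, 400, n),
            "mat": rng.uniform(2, 18, n),
            "map": rng.uniform(500, 1800, n),
            "period": period,
            "obs_year": rng.integers(years[0], years[1] + 1, n),
            "disturbed": False if disturbed is None else disturbed,
        }
    )
    for col, val in overrides.items():
        df[col] = val
    return df[PLOT_COLUMNS]


@pytest.fixture(scope="session")
def single_type_data():
    """One forest type at the default study conditions (n=2000, truth at the
    continental-average parameters, sigma=40)."""
    cfg = single_type_config(n_plots=2000, seed=11)
    plots, params = generate_dataset(cfg)
    return plots, params[0], cfg


@pytest.fixture(scope="session")
def small_fit(single_type_data):
    """A quick MCMC fit shared by tests that only need plausible draws."""
    from regrowth import run_mcmc

    plots, truth, _ = single_type_data
    sub = plots.iloc[:600]
    draws = run_mcmc(sub, chains=2, iterations=3000, seed=5)
    return sub, truth, draws
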