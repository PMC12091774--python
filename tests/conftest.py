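import numpy as np
import pandas as pd
import pytest

import tvmi
from tvmi.synth import smooth_lag_curve


@pytest.fixture(scope="session")
def small_climate():
    return tvmi.ClimateConfig(
        start_date="2014-01-01",
        end_date="2016-12-31",
        regions=(("central", 6.58), ("south", 7.74)),
        seed=11,
    )


@pytest.fixture(scope="session")
def focal_truth():
    """Truth inside the lag-spline span, pinned at the focal lags."""
    return tvmi.TrueEffect(
        upward_logor_by_lag=smooth_lag_curve(0, 0.009),
        downward_logor_by_lag=smooth_lag_curve(2, 0.003),
    )


@pytest.fixture(scope="session")
def small_cohort(small_climate, focal_truth):
    return tvmi.generate_cohort(
        climate=small_climate, truth=focal_truth, n_events=3000, seed=5
    )


@pytest.fixture(scope="session")
def small_temps(small_cohort):
    """The temperature series the cohort's events were generated from."""
    return small_cohort.temperature


@pytest.fixture(scope="session")
def small_exposures(small_temps):
    return tvmi.exposure_table_all(small_temps)


@pytest.fixture(scope="session")
def small_model_table(small_cohort, small_exposures):
    spec = tvmi.CrossbasisSpec()
    table, _ = tvmi.build_matched_sets(small_cohort.events, small_exposures)
    return tvmi.add_crossbasis(table, spec)


def make_pair_table(n_case_exposed_only: int, n_ref_exposed_only: int) -> pd.DataFrame:
    """1:1 matched pairs with one binary exposure column, discordant only."""
    rows = []
    sid = 0
    for _ in range(n_case_exposed_only):
        rows += [(sid, 1, 1.0), (sid, 0, 0.0)]
        sid += 1
    for _ in range(n_ref_exposed_only):
        rows += [(sid, 1, 0.0), (sid, 0, 1.0)]
        sid += 1
    return pd.DataFrame(rows, columns=["set_id", "case", "x"])


def random_sets(rng, n_sets=20, n_cols=2, set_size=4):
    """Random matched-set model table for likelihood-level checks."""
    rows = []
    for s in range(n_sets):
        X = rng.normal(size=(set_size, n_cols))
        case = rng.integers(set_size)
        for j in range(set_size):
            rows.append((s, int(j == case), *X[j]))
    cols = ["set_id", "case"] + [f"x{k}" for k in range(n_cols)]
    return pd.DataFrame(rows, columns=cols)


def naive_conditional_loglik(beta, table, xcols):
    """Straight-from-the-definition likelihood: per-set python loop."""
    beta = np.asarray(beta, float)
    ll = 0.0
    for _, g in table.groupby("set_id"):
        eta = g[xcols].to_numpy() @ beta
        ll += eta[g["case"].to_numpy() == 1][0] - np.log(np.exp(eta).sum())
    return ll
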