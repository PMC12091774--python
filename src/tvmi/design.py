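"""Time-stratified case-crossover design.

Each hospitalization day (case day) is compared with the other days of the
same calendar month and year that fall on the same weekday (e.g. all Mondays
in January 2016).  Depending on the month's length this yields 3 or 4
referent days, each separated from the case day by a positive multiple of 7
days — so no referent's 7-day exposure-baseline window ever overlaps the
case's index day.  Covariates are time-invariant within a stratum and are
carried unchanged onto referent rows; the design cancels them in the
conditional likelihood.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exposure import N_LAGS

__all__ = ["select_referents", "build_matched_sets", "season_of"]


def season_of(dates) -> np.ndarray:
    """Season label per date: warm = April-September, cold = October-March."""
    months = pd.DatetimeIndex(pd.to_datetime(dates)).month
    return np.where((months >= 4) & (months <= 9), "warm", "cold")


def select_referents(case_date) -> list[pd.Timestamp]:
    """All other same-weekday days in the case day's calendar month and year,
    ascending."""
    d = pd.Timestamp(case_date)
    first = (d.day - 1) % 7 + 1  # first same-weekday day-of-month
    days = range(first, d.days_in_month + 1, 7)
    return [d.replace(day=k) for k in days if k != d.day]


def build_matched_sets(
    events: pd.DataFrame,
    exposures: pd.DataFrame,
    adjusters: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long model table: one row per day of each matched set.

    Parameters
    ----------
    events : one row per hospitalization with at least ``event_id``, ``date``,
        ``area_id``; any further columns (covariates, weights) are copied onto
        every row of the event's set.
    exposures : wide exposure table (from :func:`tvmi.exposure.exposure_table`)
        keyed by (area_id, date) with tv/up/down columns for lags 0..6.
    adjusters : optional day-level frame keyed by (area_id, date) (or just
        ``date``) whose remaining columns are merged onto every row.

    Returns
    -------
    (model_table, drop_log) : the model table has ``set_id``, ``date``,
        ``case`` (1 on the case day) plus exposure, covariate and adjuster
        columns; events whose case or referent days lack complete lagged
        exposure are dropped and listed in ``drop_log`` with a reason.
    """
    events = events.reset_index(drop=True)
    if len(events) == 0:
        cols = ["set_id", "date", "area_id", "case"]
        return pd.DataFrame(columns=cols), pd.DataFrame(columns=["event_id", "reason"])

    d = pd.DatetimeIndex(pd.to_datetime(events["date"]))
    dom = d.day.to_numpy()
    dim = d.days_in_month.to_numpy()
    first = (dom - 1) % 7 + 1

    # up to 5 same-weekday days per month, as day-of-month offsets
    cand = first[:, None] + 7 * np.arange(5)[None, :]  # (n, 5)
    valid = cand <= dim[:, None]

    n = len(events)
    ev_idx = np.repeat(np.arange(n), 5)[valid.ravel()]
    day_delta = (cand - dom[:, None]).ravel()[valid.ravel()]
    dates = d[ev_idx] + pd.to_timedelta(day_delta, unit="D")

    long = events.iloc[ev_idx].reset_index(drop=True)
    long["set_id"] = ev_idx
    long["date"] = dates
    long["case"] = (day_delta == 0).astype(int)

    long = long.merge(exposures, on=["area_id", "date"], how="left", suffixes=("", "_exp"))
    if adjusters is not None:
        keys = [k for k in ("area_id", "date") if k in adjusters.columns]
        long = long.merge(adjusters, on=keys, how="left", suffixes=("", "_adj"))

    tv_cols = [f"tv_lag{l}" for l in range(N_LAGS)]
    bad_row = long[tv_cols].isna().any(axis=1)
    bad_sets = long.loc[bad_row, "set_id"].unique()

    drop_log = pd.DataFrame(
        {
            "event_id": events.loc[bad_sets, "event_id"].to_numpy()
            if "event_id" in events.columns
            else bad_sets,
            "reason": "incomplete lagged exposure for case or referent day",
        }
    )
    table = long[~long["set_id"].isin(bad_sets)].reset_index(drop=True)
    table = table.sort_values(["set_id", "date"], kind="stable").reset_index(drop=True)
    return table, drop_log
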