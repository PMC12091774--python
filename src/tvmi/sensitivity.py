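"""Sensitivity analyses as configuration-driven refits of the base model.

Variants: add a public-holiday indicator; add same-day daily mean
temperature as a 3-df natural cubic spline; add one same-day pollutant at a
time as a linear term; or recompute the exposure with a 3-day baseline
window instead of 7.  Adjusters are day-level (they vary within matched
sets, hence are identifiable); a set-constant adjuster is rejected by the
fitter with an explicit message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("tvmi")

from . import clogit
from .crossbasis import CrossbasisSpec, add_crossbasis, natural_spline_basis
from .design import build_matched_sets
from .effects import all_lag_effects
from .exposure import exposure_table_all

__all__ = ["SensitivitySpec", "run_sensitivity"]

POLLUTANTS = ("pm25", "no2", "o3")


@dataclass(frozen=True)
class SensitivitySpec:
    """One sensitivity variant; exactly one knob turned per run."""

    name: str
    holiday: bool = False
    mean_temperature_df: int | None = None  # spline df for same-day tmean
    pollutant: str | None = None  # one of POLLUTANTS, same-day linear
    window: int = 7

    def __post_init__(self):
        knobs = sum(
            [
                self.holiday,
                self.mean_temperature_df is not None,
                self.pollutant is not None,
                self.window != 7,
            ]
        )
        if knobs > 1:
            raise ValueError("one sensitivity variant per run")
        if self.pollutant is not None and self.pollutant not in POLLUTANTS:
            raise ValueError(f"unknown pollutant {self.pollutant!r}")


def run_sensitivity(
    events: pd.DataFrame,
    temps: pd.DataFrame,
    cb_spec: CrossbasisSpec,
    sens: SensitivitySpec,
    holidays: pd.DataFrame | None = None,
    pollutants: pd.DataFrame | None = None,
    base_effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Refit with the variant's adjuster (or alternative exposure window).

    Returns the 14 lag effects labelled by variant; if ``base_effects`` is
    given, a ``delta_logor`` column reports the change from the base model.
    """
    exposures = exposure_table_all(temps, window=sens.window)

    adjusters = None
    adj_cols: list[str] = []
    if sens.holiday:
        if holidays is None:
            raise ValueError("holiday variant needs a holiday calendar")
        hdates = pd.DatetimeIndex(pd.to_datetime(holidays["date"]))
        dates = pd.DatetimeIndex(pd.to_datetime(temps["date"].unique()))
        adjusters = pd.DataFrame(
            {"date": dates, "holiday": dates.isin(hdates).astype(float)}
        )
        adj_cols = ["holiday"]
    elif sens.pollutant is not None:
        if pollutants is None:
            raise ValueError("pollutant variant needs pollutant series")
        missing = pollutants[sens.pollutant].isna()
        adjusters = pollutants.loc[~missing, ["date", "area_id", sens.pollutant]].copy()
        adjusters["date"] = pd.to_datetime(adjusters["date"])
        adj_cols = [sens.pollutant]

    table, _ = build_matched_sets(events, exposures, adjusters)
    if adj_cols:
        bad_sets = table.loc[table[adj_cols].isna().any(axis=1), "set_id"].unique()
        if len(bad_sets):
            table = table[~table["set_id"].isin(bad_sets)].reset_index(drop=True)
    table = add_crossbasis(table, cb_spec)

    if sens.mean_temperature_df is not None:
        t = temps.rename(columns={"tmean_c": "tmean_day"}).copy()
        t["date"] = pd.to_datetime(t["date"])
        table = table.merge(t, on=["area_id", "date"], how="left")
        v = table["tmean_day"].to_numpy(float)
        interior = np.quantile(v, [1 / 3, 2 / 3])
        B = natural_spline_basis(
            v, interior, (v.min(), v.max()), include_intercept=False
        )
        adj_cols = [f"tmean_ns_{k}" for k in range(1, B.shape[1] + 1)]
        table[adj_cols] = B

    # a degenerate (globally constant) adjuster carries no information:
    # drop it and the refit reduces to the base model
    constant = [c for c in adj_cols if table[c].nunique() <= 1]
    if constant:
        log.info("dropping constant adjuster column(s) %s", constant)
        adj_cols = [c for c in adj_cols if c not in constant]

    xcols = cb_spec.column_names() + adj_cols
    res = clogit.fit(table, xcols)
    out = all_lag_effects(res, cb_spec)
    out.insert(0, "analysis", sens.name)
    out["n_sets"] = res.n_sets
    if base_effects is not None:
        base = base_effects.set_index(["direction", "lag"])["logor"]
        out["delta_logor"] = (
            out["logor"].to_numpy()
            - base.loc[list(zip(out["direction"], out["lag"]))].to_numpy()
        )
    return out
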