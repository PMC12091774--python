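"""Directional temperature-variability exposure.

Temperature variability (TV) on a given day is the difference between that
day's mean temperature and the plain arithmetic mean of the preceding
``window`` days (default 7, index day excluded).  A positive value is an
upward temperature shift, a negative value a downward shift; the two hinges
``up = max(tv, 0)`` and ``down = min(tv, 0)`` satisfy ``up + down = tv`` and
``up * down = 0``.  Lagged values simply shift the index day: TV at lag l on
date d equals TV at lag 0 on date d - l.

Missing temperature anywhere in a required window invalidates that
(date, lag) value rather than imputing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "MissingExposureError",
    "compute_tv",
    "split_direction",
    "exposure_table",
    "exposure_table_all",
]

N_LAGS = 7  # lags 0..6


class MissingExposureError(ValueError):
    """Raised when a requested (date, lag) lacks complete temperature history."""

    def __init__(self, date, message: str):
        super().__init__(message)
        self.date = date


@dataclass
class TemperatureSeries:
    """Per-area daily mean temperature on a complete, contiguous date index."""

    area_id: str
    values: pd.Series  # float °C, DatetimeIndex at daily frequency

    def __post_init__(self):
        idx = self.values.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValueError("temperature series needs a DatetimeIndex")
        if len(idx) == 0:
            raise ValueError("temperature series is empty")
        diffs = np.diff(idx.values.astype("datetime64[D]").astype(int))
        if np.any(diffs != 1):
            raise ValueError(
                f"area {self.area_id}: dates must be strictly increasing with "
                "step one day and no gaps"
            )
        if self.values.isna().any():
            first = self.values.index[self.values.isna()][0]
            raise MissingExposureError(
                first, f"area {self.area_id}: missing temperature on {first.date()}"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, area_id: str) -> "TemperatureSeries":
        sub = frame.loc[frame["area_id"] == area_id].sort_values("date")
        vals = pd.Series(
            sub["tmean_c"].to_numpy(float), index=pd.DatetimeIndex(sub["date"])
        )
        return cls(area_id=area_id, values=vals)


def compute_tv(series: TemperatureSeries, date, lag: int, window: int = 7) -> float:
    """TV at a single (date, lag): T(date-lag) minus the mean of the
    ``window`` days before date-lag."""
    if not 0 <= lag < N_LAGS:
        raise ValueError(f"lag must be in 0..{N_LAGS - 1}, got {lag}")
    date = pd.Timestamp(date)
    target = date - pd.Timedelta(days=lag)
    needed = pd.date_range(target - pd.Timedelta(days=window), target, freq="D")
    absent = needed.difference(series.values.index)
    if len(absent):
        raise MissingExposureError(
            absent[0],
            f"area {series.area_id}: no temperature for {absent[0].date()} "
            f"(needed for date {date.date()}, lag {lag}, window {window})",
        )
    vals = series.values.loc[needed].to_numpy()
    return float(vals[-1] - vals[:-1].mean())


def split_direction(tv: float) -> tuple[float, float]:
    """Hinge split at 0: ``(max(tv, 0), min(tv, 0))``."""
    if not np.isfinite(tv):
        raise ValueError(f"non-finite temperature variability {tv!r}")
    return (max(tv, 0.0), min(tv, 0.0))


def exposure_table(
    series: TemperatureSeries,
    dates=None,
    window: int = 7,
) -> pd.DataFrame:
    """Wide per-day exposure: tv/up/down at lags 0..6 for the requested dates.

    With ``dates=None`` every day of the series is returned and days with
    incomplete history carry NaN; with explicit dates any unsatisfiable
    request raises :class:`MissingExposureError` naming the first absent day.
    """
    t = series.values
    vals = t.to_numpy()
    # lag-0 TV for every day, then lag l by shifting; the baseline mean uses
    # the same pairwise reduction as a per-day numpy mean, so a naive loop
    # oracle reproduces these values bit for bit
    tv0 = np.full(len(vals), np.nan)
    if len(vals) > window:
        windows = np.lib.stride_tricks.sliding_window_view(vals[:-1], window)
        tv0[window:] = vals[window:] - windows.mean(axis=1)
    tv0 = pd.Series(tv0, index=t.index)
    out = pd.DataFrame({"date": t.index, "area_id": series.area_id})
    for lag in range(N_LAGS):
        tv = tv0.shift(lag).to_numpy()
        out[f"tv_lag{lag}"] = tv
    for lag in range(N_LAGS):
        tv = out[f"tv_lag{lag}"].to_numpy()
        out[f"up_lag{lag}"] = np.maximum(tv, 0.0)
        out[f"down_lag{lag}"] = np.minimum(tv, 0.0)
    out["window"] = window

    if dates is None:
        return out
    dates = pd.DatetimeIndex(pd.to_datetime(dates))
    sel = out.set_index("date")
    absent = dates.difference(sel.index)
    if len(absent):
        raise MissingExposureError(
            absent[0], f"area {series.area_id}: no series coverage for {absent[0].date()}"
        )
    sub = sel.loc[dates.rename("date")].reset_index()
    tv_cols = [f"tv_lag{l}" for l in range(N_LAGS)]
    if sub[tv_cols].isna().any().any():
        bad = sub.loc[sub[tv_cols].isna().any(axis=1), "date"].iloc[0]
        raise MissingExposureError(
            bad,
            f"area {series.area_id}: incomplete lag history for {bad.date()} "
            f"(window {window})",
        )
    return sub


def exposure_table_all(temps: pd.DataFrame, window: int = 7) -> pd.DataFrame:
    """Exposure table for every area in a long temperature frame
    (columns date, area_id, tmean_c)."""
    parts = []
    for area in sorted(temps["area_id"].unique()):
        series = TemperatureSeries.from_frame(temps, area)
        parts.append(exposure_table(series, window=window))
    return pd.concat(parts, ignore_index=True)
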