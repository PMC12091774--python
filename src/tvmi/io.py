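"""CSV contracts, pipeline configuration and run manifests.

All dates are ISO-8601.  Readers validate the schema up front and fail with
the file, line and column of the offence; duplicated (date, area_id) rows
are rejected, out-of-order dates are accepted with a log notice and sorted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("tvmi")

__all__ = [
    "CsvContractError",
    "read_csv_contract",
    "read_temperature_csv",
    "read_events_csv",
    "read_pollutants_csv",
    "read_holidays_csv",
    "write_exposure_csv",
    "PipelineConfig",
    "write_manifest",
]


class CsvContractError(ValueError):
    """Schema violation, with file / line / column context."""


def read_csv_contract(
    path,
    required: dict,
    date_cols: tuple[str, ...] = ("date",),
    unique_key: tuple[str, ...] | None = None,
    sort_by: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Read a CSV, enforce column presence/types, parse dates, check keys.

    ``required`` maps column name to a numpy-compatible dtype (or None to
    leave the column as read).  Line numbers in messages are 1-based file
    lines (header = line 1).
    """
    path = Path(path)
    if not path.exists():
        raise CsvContractError(f"{path}: file not found")
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise CsvContractError(f"{path}: missing required column '{col}'")
    for col in date_cols:
        if col not in df.columns:
            continue
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = np.flatnonzero(parsed.isna().to_numpy() & df[col].notna().to_numpy())
        if bad.size:
            raise CsvContractError(
                f"{path}: line {bad[0] + 2}, column '{col}': "
                f"bad ISO-8601 date {df[col].iloc[bad[0]]!r}"
            )
        df[col] = parsed
    for col, dtype in required.items():
        if dtype is None or col in date_cols:
            continue
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise CsvContractError(
                f"{path}: column '{col}' is not {dtype}: {exc}"
            ) from None
    if unique_key:
        dup = df.duplicated(subset=list(unique_key), keep=False)
        if dup.any():
            lines = (np.flatnonzero(dup.to_numpy()) + 2).tolist()
            raise CsvContractError(
                f"{path}: duplicated {unique_key} rows at lines {lines[:10]}"
            )
    if sort_by:
        if not df[list(sort_by)].equals(
            df[list(sort_by)].sort_values(list(sort_by), ignore_index=True)
        ):
            log.info("%s: rows out of order; sorting by %s", path, sort_by)
        df = df.sort_values(list(sort_by), kind="stable", ignore_index=True)
    return df


def read_temperature_csv(path) -> pd.DataFrame:
    df = read_csv_contract(
        path,
        {"date": None, "area_id": str, "tmean_c": float},
        unique_key=("area_id", "date"),
        sort_by=("area_id", "date"),
    )
    # contiguity per area
    for area, sub in df.groupby("area_id"):
        gaps = sub["date"].diff()
        bad = gaps.notna() & (gaps != pd.Timedelta(days=1))
        if bad.any():
            first = sub.loc[bad, "date"].iloc[0]
            raise CsvContractError(
                f"{path}: area {area}: date gap before {first.date()}"
            )
    return df


def read_events_csv(path) -> pd.DataFrame:
    return read_csv_contract(
        path,
        {"event_id": None, "date": None, "area_id": str, "subtype": str},
        sort_by=("date",),
    )


def read_pollutants_csv(path) -> pd.DataFrame:
    return read_csv_contract(
        path,
        {"date": None, "area_id": str, "pm25": float, "no2": float, "o3": float},
        unique_key=("area_id", "date"),
        sort_by=("area_id", "date"),
    )


def read_holidays_csv(path) -> pd.DataFrame:
    return read_csv_contract(path, {"date": None, "name": str})


def write_exposure_csv(exposures: pd.DataFrame, path, n_lags: int = 7) -> None:
    """Long-format exposure CSV: date, area_id, lag, tv, up, down, window."""
    frames = []
    for lag in range(n_lags):
        frames.append(
            pd.DataFrame(
                {
                    "date": pd.to_datetime(exposures["date"]).dt.strftime("%Y-%m-%d"),
                    "area_id": exposures["area_id"],
                    "lag": lag,
                    "tv": exposures[f"tv_lag{lag}"],
                    "up": exposures[f"up_lag{lag}"],
                    "down": exposures[f"down_lag{lag}"],
                    "window": exposures["window"],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Paths, crossbasis settings and analysis list for one pipeline run."""

    temperature: str = "temperature.csv"
    events: str = "events.csv"
    pollutants: str | None = None
    holidays: str | None = None
    outdir: str = "results"
    window: int = 7
    threshold: float = 0.0
    max_lag: int = 6
    lag_knots: list | None = None  # None -> evenly-spaced-log default
    subtypes: list = field(default_factory=lambda: ["total", "STEMI", "NSTEMI"])
    modifiers: list = field(default_factory=list)
    sensitivity: list = field(default_factory=list)
    seed: int = 0

    def crossbasis_spec(self):
        from .crossbasis import CrossbasisSpec

        return CrossbasisSpec(
            threshold=self.threshold,
            max_lag=self.max_lag,
            interior_knots=tuple(self.lag_knots) if self.lag_knots else None,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise CsvContractError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_manifest(path, config: PipelineConfig, **counts) -> None:
    """Machine-readable run manifest: config hash, versions, seeds, row counts."""
    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": counts,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
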