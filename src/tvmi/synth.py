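"""Synthetic Sweden-like cohorts with known lag-response truth.

Temperature per region follows a sinusoidal seasonal cycle around the
region's annual mean plus first-order autoregressive daily anomalies.  The
default climate is moment-matched to Swedish summaries: regional annual
means 3.50 / 6.58 / 7.74 °C (north / central / south), an overall daily
standard deviation near 7.8 °C, and realized upward / downward temperature
shifts with medians near +1.4 / -1.4 °C.

Hospitalization days are drawn with probability proportional to
``exp(seasonal baseline + day-of-week effects + crossbasis(truth))``
over eligible area-days — day-level thinning of a log-linear intensity,
which is all a self-matched case-crossover design needs (no explicit
non-case cohort).  Time-invariant covariates are sampled independently of
the day, so they cannot confound the self-matched estimand; configured
modifier interactions tilt the day-sampling of the carrier subgroup, giving
the analysis a recoverable interaction truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exposure import N_LAGS, exposure_table_all

__all__ = [
    "smooth_lag_curve",
    "ClimateConfig",
    "TrueEffect",
    "CovariateModel",
    "SyntheticCohort",
    "generate_temperature",
    "generate_pollutants",
    "generate_holidays",
    "generate_events",
    "generate_cohort",
    "SWEDISH_FIXED_HOLIDAYS",
]

SEASONAL_PEAK_DOY = 201  # around July 20, the warmest time of year

# fixed-date public holidays (movable feasts deliberately out of scope)
SWEDISH_FIXED_HOLIDAYS = (
    ("01-01", "New Year's Day"),
    ("01-06", "Epiphany"),
    ("05-01", "May Day"),
    ("06-06", "National Day"),
    ("12-24", "Christmas Eve"),
    ("12-25", "Christmas Day"),
    ("12-26", "Second Day of Christmas"),
    ("12-31", "New Year's Eve"),
)


def smooth_lag_curve(lag: int, value: float, spec=None) -> tuple[float, ...]:
    """A lag-response curve inside the lag-spline span, pinned at one lag.

    Returns the 7 per-lag log-ORs of the minimum-norm spline coefficient
    vector whose curve equals ``value`` at ``lag``.  Truth built this way is
    exactly representable by the analysis crossbasis, so recovery
    simulations test estimation rather than basis misspecification.
    """
    from .crossbasis import CrossbasisSpec, lag_basis

    spec = spec or CrossbasisSpec()
    G = lag_basis(spec)
    g = G[lag]
    coef = value * g / (g @ g)
    return tuple(G @ coef)


@dataclass(frozen=True)
class ClimateConfig:
    """Seasonal-plus-AR(1) climate model for a handful of regions.

    ``regions`` maps region label to annual-mean temperature (°C);
    ``seasonal_amplitude`` is the half-range of the annual sinusoid;
    ``anomaly_sd`` is the *stationary* standard deviation of the AR(1)
    daily anomaly with lag-1 autocorrelation ``ar_coefficient``.
    """

    start_date: str = "2005-01-01"
    end_date: str = "2019-12-31"
    regions: tuple[tuple[str, float], ...] = (
        ("north", 3.50),
        ("central", 6.58),
        ("south", 7.74),
    )
    seasonal_amplitude: float = 10.5
    ar_coefficient: float = 0.8
    anomaly_sd: float = 2.4
    seed: int = 0

    def __post_init__(self):
        if pd.Timestamp(self.end_date) <= pd.Timestamp(self.start_date):
            raise ValueError("end_date must fall after start_date")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("ar_coefficient must satisfy |rho| < 1 (stationarity)")
        if not self.anomaly_sd > 0:
            raise ValueError("anomaly_sd must be positive")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be nonnegative")
        if len(self.regions) == 0:
            raise ValueError("at least one region is required")


@dataclass(frozen=True)
class TrueEffect:
    """Ground-truth lag-specific log-ORs per 1 °C of directional shift.

    ``modifier_interactions`` maps a 0/1 covariate column name to a
    ``(direction, lag, delta_logor)`` triple: carriers of the covariate get
    the extra log-OR per °C at that direction and lag.
    """

    upward_logor_by_lag: tuple[float, ...] = (0.0,) * N_LAGS
    downward_logor_by_lag: tuple[float, ...] = (0.0,) * N_LAGS
    modifier_interactions: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, vals in (
            ("upward_logor_by_lag", self.upward_logor_by_lag),
            ("downward_logor_by_lag", self.downward_logor_by_lag),
        ):
            arr = np.asarray(vals, dtype=float)
            if arr.shape != (N_LAGS,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} needs exactly {N_LAGS} finite values")
        for cov, (direction, lag, delta) in self.modifier_interactions.items():
            if direction not in ("up", "down") or not 0 <= lag < N_LAGS:
                raise ValueError(f"bad modifier interaction for {cov!r}")


@dataclass(frozen=True)
class CovariateModel:
    """Prevalences for the sampled time-invariant covariates."""

    p_male: float = 0.655
    age_mean: float = 70.6
    age_sd: float = 12.0
    p_diabetes: float = 0.22
    p_recurrent: float = 0.30
    p_smoker: float = 0.35
    p_stemi: float = 0.30  # subtype: STEMI vs NSTEMI


@dataclass
class SyntheticCohort:
    temperature: pd.DataFrame
    pollutants: pd.DataFrame
    holidays: pd.DataFrame
    events: pd.DataFrame
    truth: TrueEffect
    climate: ClimateConfig
    log: dict

    def to_csvs(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in (
            ("temperature", self.temperature),
            ("pollutants", self.pollutants),
            ("holidays", self.holidays),
            ("events", self.events),
        ):
            f = frame.copy()
            if "date" in f.columns:
                f["date"] = pd.to_datetime(f["date"]).dt.strftime("%Y-%m-%d")
            f.to_csv(out / f"{name}.csv", index=False)


def _seasonal(dates: pd.DatetimeIndex, amplitude: float) -> np.ndarray:
    doy = dates.dayofyear.to_numpy()
    return amplitude * np.cos(2 * np.pi * (doy - SEASONAL_PEAK_DOY) / 365.25)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) with marginal standard deviation ``sd``."""
    innov_sd = sd * np.sqrt(1 - rho**2)
    e = rng.normal(0.0, innov_sd, size=n)
    e[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -rho], e)


def generate_temperature(config: ClimateConfig) -> pd.DataFrame:
    """Daily mean temperature per region: seasonal cycle + AR(1) anomalies."""
    dates = pd.date_range(config.start_date, config.end_date, freq="D")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    parts = []
    for label, mean_c in config.regions:
        anom = _ar1(rng, len(dates), config.ar_coefficient, config.anomaly_sd)
        tmean = mean_c + _seasonal(dates, config.seasonal_amplitude) + anom
        parts.append(
            pd.DataFrame({"date": dates, "area_id": label, "tmean_c": tmean})
        )
    return pd.concat(parts, ignore_index=True)


def generate_pollutants(
    temps: pd.DataFrame,
    seed: int = 0,
    means: dict | None = None,
    ar: float = 0.6,
    log_sd: float = 0.4,
) -> pd.DataFrame:
    """Lognormal AR(1) pollutant series per area, independent of temperature."""
    means = means or {"pm25": 6.0, "no2": 10.0, "o3": 55.0}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    parts = []
    for area in sorted(temps["area_id"].unique()):
        dates = pd.DatetimeIndex(
            pd.to_datetime(temps.loc[temps["area_id"] == area, "date"])
        )
        cols = {"date": dates, "area_id": area}
        for name, mu in means.items():
            z = _ar1(rng, len(dates), ar, log_sd)
            cols[name] = mu * np.exp(z - log_sd**2 / 2)
        parts.append(pd.DataFrame(cols))
    return pd.concat(parts, ignore_index=True)


def generate_holidays(years, holiday_list=SWEDISH_FIXED_HOLIDAYS) -> pd.DataFrame:
    """Fixed-date holiday calendar for the given years."""
    rows = [
        {"date": pd.Timestamp(f"{y}-{mmdd}"), "name": name}
        for y in years
        for mmdd, name in holiday_list
    ]
    return pd.DataFrame(rows, columns=["date", "name"])


def generate_events(
    temps: pd.DataFrame,
    truth: TrueEffect,
    n_events: int,
    covariate_model: CovariateModel | None = None,
    seed: int = 0,
    seasonal_baseline: float = 0.0,
    dow_effects: tuple[float, ...] | None = None,
    mean_temp_logor: float = 0.0,
    window: int = 7,
) -> pd.DataFrame:
    """Sample hospitalization records from the log-linear day intensity.

    ``seasonal_baseline`` is the log-intensity amplitude of an annual
    sinusoid (peaking in winter, as MI incidence does); ``dow_effects`` are
    optional log-intensity offsets for Monday..Sunday.  Both are nuisance
    structure the time-stratified matching must absorb.  A nonzero
    ``mean_temp_logor`` couples the intensity linearly to the same-day mean
    temperature, creating the confounding scenario the mean-temperature
    sensitivity adjustment is meant to handle.
    """
    if n_events < 0:
        raise ValueError("n_events must be nonnegative")
    cm = covariate_model or CovariateModel()
    exposures = exposure_table_all(temps, window=window)
    tv_cols = [f"tv_lag{l}" for l in range(N_LAGS)]
    elig = exposures.dropna(subset=tv_cols).reset_index(drop=True)
    if len(elig) == 0 or (n_events > 0 and len(elig) < 1):
        raise ValueError("temperature series too short: no eligible event days")

    dates = pd.DatetimeIndex(elig["date"])
    up = np.maximum(elig[tv_cols].to_numpy(), 0.0)  # °C above 7-day mean
    dn = np.maximum(-elig[tv_cols].to_numpy(), 0.0)  # °C below 7-day mean
    eta = up @ np.asarray(truth.upward_logor_by_lag) + dn @ np.asarray(
        truth.downward_logor_by_lag
    )
    if seasonal_baseline:
        # winter peak: flip the sign of the temperature seasonal term
        eta = eta - _seasonal(dates, seasonal_baseline)
    if dow_effects is not None:
        eta = eta + np.asarray(dow_effects, dtype=float)[dates.weekday]
    if mean_temp_logor:
        tmean = (
            elig.merge(temps, on=["area_id", "date"], how="left")["tmean_c"]
            .to_numpy(float)
        )
        eta = eta + mean_temp_logor * tmean

    cols = ["event_id", "date", "area_id", "region", "subtype", "male", "age",
            "age65", "diabetes", "recurrent", "smoker", "season"]
    if n_events == 0:
        return pd.DataFrame(columns=cols)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    cov = pd.DataFrame(
        {
            "male": rng.random(n_events) < cm.p_male,
            "diabetes": rng.random(n_events) < cm.p_diabetes,
            "recurrent": rng.random(n_events) < cm.p_recurrent,
            "smoker": rng.random(n_events) < cm.p_smoker,
        }
    ).astype(int)
    age = np.clip(rng.normal(cm.age_mean, cm.age_sd, n_events), 30, 100)
    cov["age"] = np.round(age, 1)
    cov["age65"] = (age >= 65).astype(int)
    cov["subtype"] = np.where(rng.random(n_events) < cm.p_stemi, "STEMI", "NSTEMI")

    # modifier carriers sample their day from a tilted intensity
    mod_cols = sorted(truth.modifier_interactions)
    basis = {"up": up, "down": dn}
    day_idx = np.empty(n_events, dtype=int)
    patterns = (
        cov[mod_cols].apply(tuple, axis=1)
        if mod_cols
        else pd.Series([()] * n_events)
    )
    for pattern, members in patterns.groupby(patterns).groups.items():
        eta_g = eta.copy()
        key = pattern if isinstance(pattern, tuple) else (pattern,)
        for flag, name in zip(key, mod_cols):
            if flag:
                direction, lag, delta = truth.modifier_interactions[name]
                eta_g = eta_g + delta * basis[direction][:, lag]
        p = np.exp(eta_g - eta_g.max())
        p /= p.sum()
        day_idx[np.asarray(members)] = rng.choice(len(elig), size=len(members), p=p)

    ev = cov.copy()
    ev.insert(0, "event_id", np.arange(n_events))
    ev.insert(1, "date", dates[day_idx])
    ev.insert(2, "area_id", elig["area_id"].to_numpy()[day_idx])
    ev.insert(3, "region", ev["area_id"])
    from .design import season_of

    ev["season"] = season_of(ev["date"])
    return ev[cols].sort_values("date", kind="stable").reset_index(drop=True)


def generate_cohort(
    climate: ClimateConfig | None = None,
    truth: TrueEffect | None = None,
    n_events: int = 50_000,
    covariate_model: CovariateModel | None = None,
    seed: int = 0,
    seasonal_baseline: float = 0.3,
    window: int = 7,
) -> SyntheticCohort:
    """End-to-end cohort: climate, pollutants, holidays and events.

    All randomness descends from ``seed``; the same seed reproduces the
    cohort bit-for-bit.
    """
    ss = np.random.SeedSequence(seed)
    s_clim, s_poll, s_ev = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    climate = replace(climate or ClimateConfig(), seed=s_clim)
    truth = truth or TrueEffect()
    temps = generate_temperature(climate)
    polls = generate_pollutants(temps, seed=s_poll)
    years = range(
        pd.Timestamp(climate.start_date).year, pd.Timestamp(climate.end_date).year + 1
    )
    holidays = generate_holidays(list(years))
    events = generate_events(
        temps,
        truth,
        n_events,
        covariate_model=covariate_model,
        seed=s_ev,
        seasonal_baseline=seasonal_baseline,
        window=window,
    )
    log = {
        "seed": seed,
        "n_events": n_events,
        "seasonal_baseline": seasonal_baseline,
        "window": window,
        "climate": climate,
    }
    return SyntheticCohort(temps, polls, holidays, events, truth, climate, log)
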