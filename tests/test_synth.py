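import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tvmi
from tvmi.synth import smooth_lag_curve


class TestGenerateTemperature:
    def test_same_seed_is_bit_identical(self, small_climate):
        a = tvmi.generate_temperature(small_climate)
        b = tvmi.generate_temperature(small_climate)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_limit_is_seasonal_cycle_at_regional_mean(self):
        cfg = tvmi.ClimateConfig(
            start_date="2010-01-01",
            end_date="2010-12-31",
            regions=(("r", 5.0),),
            seasonal_amplitude=0.0,
            anomaly_sd=1e-9,
        )
        t = tvmi.generate_temperature(cfg)
        np.testing.assert_allclose(t["tmean_c"], 5.0, atol=1e-7)

    def test_moments_match_configuration_over_15_years(self):
        cfg = tvmi.ClimateConfig(seed=123)  # 2005-2019 defaults
        t = tvmi.generate_temperature(cfg)
        for region, mean_c in cfg.regions:
            sub = t.loc[t["area_id"] == region, "tmean_c"]
            assert sub.mean() == pytest.approx(mean_c, abs=0.5)
        # lag-1 autocorrelation of anomalies (seasonal cycle removed)
        sub = t[t["area_id"] == "central"].copy()
        doy = pd.DatetimeIndex(sub["date"]).dayofyear
        anom = sub["tmean_c"].to_numpy() - (
            6.58
            + cfg.seasonal_amplitude
            * np.cos(2 * np.pi * (doy - 201) / 365.25)
        )
        r1 = np.corrcoef(anom[:-1], anom[1:])[0, 1]
        assert r1 == pytest.approx(cfg.ar_coefficient, abs=0.05)

    def test_invalid_configurations_rejected(self):
        with pytest.raises(ValueError):
            tvmi.ClimateConfig(start_date="2010-01-01", end_date="2009-01-01")
        with pytest.raises(ValueError):
            tvmi.ClimateConfig(ar_coefficient=1.0)
        with pytest.raises(ValueError):
            tvmi.ClimateConfig(anomaly_sd=0.0)

    def test_realized_shift_medians_bracket_swedish_summaries(self):
        t = tvmi.generate_temperature(tvmi.ClimateConfig(seed=2024))
        tv0 = tvmi.exposure_table_all(t)["tv_lag0"].dropna()
        up_median = tv0[tv0 > 0].median()
        down_median = tv0[tv0 < 0].median()
        assert up_median == pytest.approx(1.40, abs=0.7)
        assert down_median == pytest.approx(-1.38, abs=0.7)


class TestGenerateEvents:
    def test_zero_events_gives_empty_frame(self, small_temps):
        ev = tvmi.generate_events(small_temps, tvmi.TrueEffect(), 0)
        assert len(ev) == 0 and "date" in ev.columns

    def test_null_truth_dates_uniform_over_eligible_days(self, small_temps):
        ev = tvmi.generate_events(small_temps, tvmi.TrueEffect(), 10_000, seed=9)
        counts = ev.groupby(["area_id", "date"]).size()
        elig = tvmi.exposure_table_all(small_temps).dropna(subset=["tv_lag6"])
        n_days = len(elig)
        # chi-square GOF against the uniform over all eligible day-area cells
        full = counts.reindex(
            pd.MultiIndex.from_frame(elig[["area_id", "date"]]), fill_value=0
        ).to_numpy()
        chi2 = ((full - full.mean()) ** 2 / full.mean()).sum()
        p = stats.chi2.sf(chi2, n_days - 1)
        assert p > 0.01

    def test_upward_effect_raises_event_frequency_with_same_day_shift(
        self, small_temps
    ):
        truth = tvmi.TrueEffect(upward_logor_by_lag=(0.2, 0, 0, 0, 0, 0, 0))
        ev = tvmi.generate_events(small_temps, truth, 20_000, seed=10)
        expo = tvmi.exposure_table_all(small_temps).dropna(subset=["tv_lag6"])
        counts = (
            ev.groupby(["area_id", "date"])
            .size()
            .reindex(pd.MultiIndex.from_frame(expo[["area_id", "date"]]), fill_value=0)
        )
        up0 = np.maximum(expo["tv_lag0"].to_numpy(), 0)
        rho = stats.spearmanr(up0, counts.to_numpy()).statistic
        assert rho > 0.05

    def test_requesting_more_than_zero_events_on_short_series_errors(self):
        t = tvmi.generate_temperature(
            tvmi.ClimateConfig(start_date="2020-01-01", end_date="2020-01-10")
        )
        with pytest.raises(ValueError, match="eligible"):
            tvmi.generate_events(t, tvmi.TrueEffect(), 5)


class TestGenerateHolidays:
    def test_fixed_dates_present(self):
        h = tvmi.generate_holidays([2016])
        assert pd.Timestamp("2016-01-01") in set(h["date"])

    def test_empty_year_list_gives_empty_calendar(self):
        assert len(tvmi.generate_holidays([])) == 0

    def test_disjoint_year_lists_give_disjoint_calendars(self):
        a = set(tvmi.generate_holidays([2014, 2015])["date"])
        b = set(tvmi.generate_holidays([2016])["date"])
        assert a.isdisjoint(b)


class TestCohort:
    def test_cohort_reproducible_bit_for_bit(self, small_climate, focal_truth):
        kw = dict(climate=small_climate, truth=focal_truth, n_events=500, seed=77)
        a, b = tvmi.generate_cohort(**kw), tvmi.generate_cohort(**kw)
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.temperature, b.temperature)
        pd.testing.assert_frame_equal(a.pollutants, b.pollutants)

    def test_event_invariants(self, small_cohort):
        areas = set(small_cohort.temperature["area_id"])
        assert set(small_cohort.events["area_id"]) <= areas
        start = pd.Timestamp(small_cohort.climate.start_date)
        # every event has complete lag-0..6 exposure: >= 13 days after start
        assert (small_cohort.events["date"] >= start + pd.Timedelta(days=13)).all()

    def test_smooth_lag_curve_is_pinned_and_in_span(self):
        from tvmi.crossbasis import CrossbasisSpec, lag_basis

        curve = np.asarray(smooth_lag_curve(2, 0.003))
        assert curve[2] == pytest.approx(0.003, abs=1e-12)
        G = lag_basis(CrossbasisSpec())
        coef, *_ = np.linalg.lstsq(G, curve, rcond=None)
        np.testing.assert_allclose(G @ coef, curve, atol=1e-12)


def test_null_truth_estimates_center_on_zero(small_climate):
    """With zero truth the fitted focal-lag log-ORs are unbiased.

    Mean over replicates within 3 Monte-Carlo standard errors of zero.
    """
    spec = tvmi.CrossbasisSpec()
    est = {"up": [], "down": []}
    for seed in range(100):
        coh = tvmi.generate_cohort(
            climate=small_climate, truth=tvmi.TrueEffect(), n_events=400, seed=seed
        )
        expo = tvmi.exposure_table_all(coh.temperature)
        table, _ = tvmi.build_matched_sets(coh.events, expo)
        table = tvmi.add_crossbasis(table, spec)
        fit = tvmi.fit(table, spec.column_names())
        est["up"].append(tvmi.lag_effect(fit, spec, "up", 0).logor)
        est["down"].append(tvmi.lag_effect(fit, spec, "down", 2).logor)
    for direction, vals in est.items():
        vals = np.asarray(vals)
        mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * mc_se, direction
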