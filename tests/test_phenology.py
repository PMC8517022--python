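import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bloomsat import mapping, phenology


def _dates_daily(n=365, start=dt.date(2019, 1, 1)):
    return [start + dt.timedelta(days=i) for i in range(n)]


def _monthly(values, det=None, obs=None):
    values = np.asarray(values, float)
    if obs is None:
        obs = np.where(np.isfinite(values), 10, 0)
    if det is None:
        det = np.rint(np.nan_to_num(values) * obs).astype(int)
    return phenology.MonthlySeries(values, obs, det)


class TestMonthlySeries:
    def test_normalization_arithmetic(self):
        # 2 detections among 8 cloud-free March observations -> 0.25
        dates, states = [], []
        for i in range(8):
            dates.append(dt.date(2019, 3, 1 + i))
            states.append(mapping.DETECTED if i < 2 else mapping.CLEAR)
        ms = phenology.monthly_series(dates, states)
        assert ms.values[2] == pytest.approx(0.25)
        assert ms.obs_counts[2] == 8 and ms.detection_counts[2] == 2

    def test_pools_across_years(self):
        dates = [dt.date(2018, 3, 10), dt.date(2019, 3, 10)]
        states = [mapping.DETECTED, mapping.CLEAR]
        ms = phenology.monthly_series(dates, states)
        assert ms.values[2] == pytest.approx(0.5)

    def test_no_detections_all_zero(self):
        dates = _dates_daily(60)
        ms = phenology.monthly_series(dates, [mapping.CLEAR] * 60)
        assert np.nansum(ms.values) == 0

    def test_all_cloudy_undefined(self):
        dates = _dates_daily(40)
        ms = phenology.monthly_series(dates, [mapping.CLOUD] * 40)
        assert np.isnan(ms.values).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            phenology.monthly_series([], [])


class TestCleanSeries:
    def test_pixel_with_few_detections_excluded(self):
        ms = _monthly([0.1] + [0] * 11, det=[3] + [0] * 11)
        assert phenology.clean_series(ms) is None

    def test_isolated_peak_zeroed(self):
        # March value from 1 detection, February and April empty
        vals = [0, 0, 0.1, 0, 0, 0.5, 0.6, 0, 0, 0, 0, 0]
        det = [0, 0, 1, 0, 0, 5, 6, 0, 0, 0, 0, 0]
        cleaned = phenology.clean_series(_monthly(vals, det=det))
        assert cleaned.values[2] == 0.0

    def test_peak_with_occupied_neighbor_kept(self):
        vals = [0, 0, 0.1, 0.5, 0, 0, 0, 0, 0, 0, 0, 0]
        det = [0, 0, 2, 5, 0, 0, 0, 0, 0, 0, 0, 0]
        cleaned = phenology.clean_series(_monthly(vals, det=det))
        assert cleaned.values[2] == pytest.approx(1.0)  # x10 scaling

    def test_scaling_and_value_weights(self):
        vals = [0, 0, 0.4, 0.5, 0, 0, 0, 0, 0, 0, 0, 0]
        cleaned = phenology.clean_series(_monthly(vals))
        assert cleaned.values[2] == pytest.approx(4.0)
        assert cleaned.weights[2] == pytest.approx(4.0)

    def test_shoulders_at_minus_015_of_max(self):
        vals = [0, 0, 0.2, 0.4, 0.3, 0, 0, 0, 0, 0, 0, 0]
        cleaned = phenology.clean_series(_monthly(vals))
        assert cleaned.shoulder_value == pytest.approx(-0.15 * 4.0)
        assert cleaned.values[1] == pytest.approx(-0.6)   # before run
        assert cleaned.values[5] == pytest.approx(-0.6)   # after run
        assert cleaned.weights[1] == 1.0 and cleaned.weights[5] == 1.0

    def test_circular_shoulders_across_year_boundary(self):
        vals = [0.4, 0.2, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0.3]
        cleaned = phenology.clean_series(_monthly(vals))
        assert cleaned.values[10] == pytest.approx(-0.15 * 4.0)  # November
        assert cleaned.values[2] == pytest.approx(-0.15 * 4.0)   # March

    def test_replication_periodicity(self):
        vals = [0, 0, 0.2, 0.4, 0.3, 0, 0, 0, 0, 0, 0, 0]
        cleaned = phenology.clean_series(_monthly(vals))
        assert np.array_equal(cleaned.values[:12], cleaned.values[12:24])
        assert np.array_equal(cleaned.weights[:12], cleaned.weights[24:])

    def test_zero_months_have_zero_weight(self):
        vals = [0, 0, 0.2, 0.4, 0.3, 0, 0, 0, 0, 0, 0, 0]
        cleaned = phenology.clean_series(_monthly(vals))
        zero = cleaned.values == 0
        assert np.all(cleaned.weights[zero] == 0)


class TestFitBloomModel:
    def test_exact_recovery_of_annual_harmonic(self):
        t = np.arange(1, 37, dtype=float)
        y = 1.0 + np.sin(2 * np.pi * t / 12)
        cleaned = phenology.CleanedSeries(y, np.ones(36), 0.0)
        fit = phenology.fit_bloom_model(cleaned)
        assert fit.bloom0 == pytest.approx(1.0, abs=1e-6)
        assert fit.pow0 == pytest.approx(1.0, abs=1e-6)
        assert fit.p12 == pytest.approx(1.0, abs=1e-6)
        assert fit.p4 == pytest.approx(0.0, abs=1e-6)
        assert fit.rho12 == pytest.approx(0.0, abs=1e-6)
        assert fit.weighted_r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_degenerates_cleanly(self):
        cleaned = phenology.CleanedSeries(np.full(36, 2.5), np.ones(36), 0.0)
        fit = phenology.fit_bloom_model(cleaned)
        assert fit.bloom0 == pytest.approx(2.5, abs=1e-8)
        assert fit.pow0 == pytest.approx(0.0, abs=1e-8)
        assert fit.weighted_r2 == 1.0
        assert fit.p4 + fit.p6 + fit.p12 == pytest.approx(1.0)

    def test_simplex_constraint_holds(self, rng):
        for _ in range(20):
            y = rng.normal(0, 1, 36)
            w = rng.uniform(0.1, 5, 36)
            fit = phenology.fit_bloom_model(
                phenology.CleanedSeries(y, w, 0.0))
            assert fit.p4 + fit.p6 + fit.p12 == pytest.approx(1.0, abs=1e-9)
            assert min(fit.p4, fit.p6, fit.p12) >= 0

    def test_nonlinear_parameterization_matches_linear_solution(self, rng):
        """The amplitude/phase form must reproduce the exact weighted linear
        least-squares fitted values to 1e-8."""
        t = np.arange(1, 37, dtype=float)
        X = np.column_stack(
            [np.ones(36)]
            + [f(2 * np.pi * t / p) for p in (4, 6, 12)
               for f in (np.sin, np.cos)])
        for _ in range(10):
            y = rng.normal(0, 1, 36)
            w = rng.uniform(0.1, 5, 36)
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            fit = phenology.fit_bloom_model(
                phenology.CleanedSeries(y, w, 0.0))
            assert np.allclose(fit.predict(t), X @ beta, atol=1e-8)

    def test_parameter_recovery_from_noisy_simulation(self, rng):
        # all three harmonics present: a zero-amplitude component would
        # make its (non-negative) amplitude estimate biased by construction
        truth = dict(bloom0=0.5, pow0=2.0, p12=0.5, p6=0.3, p4=0.2,
                     rho12=1.0, rho6=0.4, rho4=-0.7)
        t = np.arange(1, 37, dtype=float)
        signal = truth["bloom0"] + truth["pow0"] * (
            truth["p12"] * np.sin(2 * np.pi * t / 12 + truth["rho12"])
            + truth["p6"] * np.sin(2 * np.pi * t / 6 + truth["rho6"])
            + truth["p4"] * np.sin(2 * np.pi * t / 4 + truth["rho4"]))
        est = {k: [] for k in ("bloom0", "pow0", "p12", "p6", "p4",
                               "rho12", "rho6", "rho4")}
        for _ in range(100):
            y = signal + rng.normal(0, 0.05, 36)
            fit = phenology.fit_bloom_model(
                phenology.CleanedSeries(y, np.ones(36), 0.0))
            for k in est:
                est[k].append(getattr(fit, k))
        for k, values in est.items():
            values = np.asarray(values)
            se = values.std(ddof=1) / np.sqrt(values.size)
            assert abs(values.mean() - truth[k]) <= 3 * max(se, 1e-4), k

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            phenology.fit_bloom_model(
                phenology.CleanedSeries(np.ones(36), np.zeros(36), 0.0))


class TestReconstructDaily:
    def test_annual_harmonic_peaks_at_t_equals_3(self):
        fit = phenology.BloomFit(0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
        daily = phenology.reconstruct_daily(fit)
        # independent argmax: evaluate sin on the day->t mapping directly
        days = np.arange(1, 366)
        expected = days[np.argmax(
            np.sin(2 * np.pi * phenology.day_to_month_time(days) / 12))]
        assert daily.argmax() + 1 == expected

    def test_zero_weight_months_zeroed_and_no_negatives(self):
        fit = phenology.BloomFit(0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
        zero_months = np.zeros(12, bool)
        zero_months[5] = True
        daily = phenology.reconstruct_daily(fit, zero_months)
        assert daily.min() >= 0
        june = phenology.month_of_day(np.arange(1, 366)) == 6
        assert np.all(daily[june] == 0)

    def test_all_months_zero_weight(self):
        fit = phenology.BloomFit(5.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
        daily = phenology.reconstruct_daily(fit, np.ones(12, bool))
        assert np.array_equal(daily, np.zeros(365))


class TestExtractEvents:
    def test_single_bump(self):
        days = np.arange(1, 366)
        daily = np.clip(5 - 0.01 * (days - 100.0) ** 2, 0, None)
        events = phenology.extract_bloom_events(daily)
        assert len(events) == 1
        ev = events[0]
        assert ev.peak_day == 100
        assert ev.start_day < 100 < ev.end_day
        assert ev.peak_value == pytest.approx(5.0)

    def test_two_well_separated_lobes(self):
        days = np.arange(1, 366, dtype=float)
        daily = np.clip(np.sin(2 * np.pi * days / 182.5), 0, None)
        events = phenology.extract_bloom_events(daily)
        assert len(events) == 2

    def test_all_zero_empty(self):
        assert phenology.extract_bloom_events(np.zeros(365)) == []

    def test_constant_positive_no_events(self):
        assert phenology.extract_bloom_events(np.ones(365)) == []

    def test_wraparound_event(self):
        days = np.arange(1, 366)
        delta = (days - 360.0 + 182.5) % 365 - 182.5
        daily = np.clip(4 - 0.005 * delta ** 2, 0, None)
        events = phenology.extract_bloom_events(daily)
        assert len(events) == 1
        ev = events[0]
        assert ev.peak_day == 360
        assert ev.start_day > ev.end_day  # event straddles the year end
        assert ev.duration_days < 365

    def test_at_most_three_peaks_for_any_fit(self, rng):
        """Dense evaluation: the three-harmonic family cannot produce more
        than three blooming peaks per year."""
        for _ in range(50):
            amps = rng.uniform(0, 1, 3)
            p = amps / amps.sum()
            fit = phenology.BloomFit(
                rng.normal(0, 1), rng.uniform(0, 3), *p,
                *rng.uniform(-np.pi, np.pi, 3), 1.0)
            daily = phenology.reconstruct_daily(fit)
            events = phenology.extract_bloom_events(daily, fit)
            assert len(events) <= 3


class TestShiftEquivariance:
    @given(shift=st.integers(1, 11))
    @settings(max_examples=11, deadline=None)
    def test_month_shift_moves_events(self, shift):
        vals = np.array([0, 0, 0.2, 0.6, 0.8, 0.4, 0, 0, 0, 0, 0, 0])
        det = np.rint(vals * 30).astype(int)
        obs = np.full(12, 30)
        base = phenology.analyze_pixel(
            phenology.MonthlySeries(vals, obs, det))
        shifted = phenology.analyze_pixel(phenology.MonthlySeries(
            np.roll(vals, shift), obs, np.roll(det, shift)))
        fit0, _, ev0 = base
        fit1, _, ev1 = shifted
        assert fit1.pow0 == pytest.approx(fit0.pow0, abs=1e-6)
        assert fit1.p12 == pytest.approx(fit0.p12, abs=1e-6)
        assert fit1.weighted_r2 == pytest.approx(fit0.weighted_r2, abs=1e-6)
        assert len(ev0) == len(ev1) == 1
        delta_days = shift * 365 / 12
        moved = (ev0[0].peak_day - 1 + delta_days) % 365 + 1
        assert abs(((ev1[0].peak_day - moved + 182.5) % 365) - 182.5) <= 1.0


def test_analyze_pixel_excludes_sparse_pixels():
    vals = [0.1] + [0] * 11
    ms = _monthly(vals, det=[2] + [0] * 11, obs=[20] + [10] * 11)
    assert phenology.analyze_pixel(ms) is None
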