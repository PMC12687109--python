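"""Thermal limits, heat-event detection and climate-suitability rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heatland.heat_events import (BaselineMaxima, EventMetrics,
                                  HeatEventConfig, MissingSeriesError,
                                  annual_metrics, baseline_maxima,
                                  climate_suitable, combine_gcms,
                                  detect_events, event_metrics,
                                  suitable_years, thermal_limit)


def brute_force_events(values, t_star, min_run):
    """Day-by-day scan, the independent oracle for detect_events."""
    events, i = [], 0
    while i < len(values):
        if values[i] > t_star:
            j = i
            while j < len(values) and values[j] > t_star:
                j += 1
            if j - i >= min_run:
                events.append((i, j - i, max(values[i:j]) - t_star))
            i = j
        else:
            i += 1
    return events


class TestThermalLimit:
    def test_constant_series(self):
        assert thermal_limit({0: np.full(400, 30.0)}) == pytest.approx(30.0)

    def test_spatial_maximum(self):
        series = {0: np.full(500, 31.2), 1: np.full(500, 33.5)}
        assert thermal_limit(series) == pytest.approx(33.5)

    def test_linear_interpolation_percentile(self):
        # 101 equally likely values 1..101: p99 = 100 under linear rule
        assert thermal_limit({0: np.arange(1.0, 102.0)}) == pytest.approx(100.0)

    def test_missing_range_cell_raises(self):
        with pytest.raises(MissingSeriesError):
            thermal_limit({0: np.zeros(10)}, range_cells=[0, 1])

    def test_monotone_in_range_extent(self, rng):
        cells = {i: rng.normal(20 + i, 3, size=2000) for i in range(5)}
        limits = [thermal_limit(cells, range_cells=list(range(k + 1)))
                  for k in range(5)]
        assert all(b >= a for a, b in zip(limits, limits[1:]))


class TestDetectEvents:
    def test_five_day_run_is_not_an_event(self):
        v = np.zeros(30)
        v[10:15] = 5.0           # exactly five days above
        assert detect_events(v, 0.0, min_run=6) == []

    def test_two_qualifying_runs(self):
        v = np.zeros(365)
        v[10:18] = 2.0           # 8 days
        v[50:55] = 2.0           # 5 days: dropped
        v[200:207] = 1.5         # 7 days
        evts = detect_events(v, 0.0, min_run=6)
        assert [(e.start_day, e.length) for e in evts] == [(10, 8), (200, 7)]

    def test_no_exceedance(self):
        assert detect_events(np.full(365, 10.0), 15.0) == []

    def test_exceedance_is_strict(self):
        v = np.full(20, 1.0)
        assert detect_events(v, 1.0, min_run=6) == []

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), min_run=st.integers(1, 10))
    def test_matches_bruteforce_scan(self, seed, min_run):
        r = np.random.default_rng(seed)
        v = r.normal(0, 2, size=365).cumsum() * 0.2 + r.normal(0, 1, 365)
        t = float(np.quantile(v, r.uniform(0.3, 0.98)))
        got = [(e.start_day, e.length, e.max_exceedance)
               for e in detect_events(v, t, min_run)]
        expect = brute_force_events(v, t, min_run)
        assert [(s, l) for s, l, _ in got] == [(s, l) for s, l, _ in expect]
        np.testing.assert_allclose([m for *_, m in got],
                                   [m for *_, m in expect])


class TestEventMetrics:
    def test_empty(self):
        m = event_metrics([])
        assert (m.frequency, m.duration, m.intensity) == (0, 0, 0.0)

    def test_longest_and_max(self):
        v = np.zeros(365)
        v[0:8] = 1.5
        v[20:27] = 2.0
        m = event_metrics(detect_events(v, 0.0))
        assert (m.frequency, m.duration, m.intensity) == (2, 8, 2.0)

    def test_single_marginal_event(self):
        v = np.zeros(30)
        v[5:11] = 0.1
        m = event_metrics(detect_events(v, 0.0))
        assert (m.frequency, m.duration) == (1, 6)
        assert m.intensity == pytest.approx(0.1)

    def test_total_days_and_mean_exceedance_variants(self):
        cfg = HeatEventConfig(duration_metric="total",
                              intensity_metric="mean")
        v = np.zeros(365)
        v[0:8] = 2.0      # 8 days at +2
        v[20:26] = 1.0    # 6 days at +1
        m = event_metrics(detect_events(v, 0.0), cfg)
        assert m.duration == 14
        assert m.intensity == pytest.approx((8 * 2 + 6 * 1) / 14)


class TestAnnualMetrics:
    def test_run_split_at_year_boundary(self):
        v = np.zeros(365 * 2)
        v[360:372] = 5.0   # 5 days in year 0, 7 days in year 1
        m = annual_metrics(v, 0.0)
        assert m[0].tolist() == [0, 0, 0]          # 5-day stub: no event
        assert m[1, 0] == 1 and m[1, 1] == 7

    def test_matches_per_year_detection(self, rng):
        v = rng.normal(25, 4, size=365 * 5)
        t = float(np.quantile(v, 0.9))
        m = annual_metrics(v, t)
        for yr in range(5):
            year_vals = v[yr * 365:(yr + 1) * 365]
            ref = event_metrics(detect_events(year_vals, t))
            assert m[yr, 0] == ref.frequency
            assert m[yr, 1] == ref.duration
            assert m[yr, 2] == pytest.approx(ref.intensity)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            annual_metrics(np.zeros(100), 0.0)

    @pytest.mark.parametrize("delta", [0.5, 2.0, 5.0])
    def test_uniform_warming_never_decreases_metrics(self, rng, delta):
        v = rng.normal(25, 4, size=365 * 3) + np.linspace(0, 3, 365 * 3)
        t = float(np.quantile(v, 0.95))
        base = annual_metrics(v, t)
        warm = annual_metrics(v + delta, t)
        assert np.all(warm >= base - 1e-12)


class TestSuitability:
    def test_all_zero_metrics_suitable(self):
        b = BaselineMaxima(0, 0, 0)
        assert climate_suitable((0, 0, 0), b)

    def test_equality_remains_suitable(self):
        b = BaselineMaxima(2, 6, 1.0)
        assert climate_suitable((2, 6, 1.0), b)

    def test_any_strict_exceedance_unsuitable(self):
        b = BaselineMaxima(2, 10, 2.0)
        assert not climate_suitable((3, 6, 0.5), b)
        assert not climate_suitable((2, 11, 0.5), b)
        assert not climate_suitable((2, 10, 2.1), b)

    def test_baseline_maxima_over_table(self):
        table = np.array([[[0, 0, 0.0], [1, 6, 0.5]],
                          [[3, 8, 0.2], [0, 0, 0.0]]])
        b = baseline_maxima(table)
        assert (b.max_frequency, b.max_duration, b.max_intensity) == \
            (3, 8, 0.5)

    def test_empty_table(self):
        b = baseline_maxima(np.zeros((0, 3)))
        assert b.as_array().tolist() == [0, 0, 0]

    def test_series_never_unsuitable_under_own_maxima(self):
        """A baseline can contain events above the series' own p99."""
        v = np.zeros(365 * 20)
        v[100:110] = 5.0          # clustered heat: 10 days above the p99 (=0)
        t = float(np.quantile(v, 0.99))
        assert t == 0.0
        m = annual_metrics(v, t)
        assert m[:, 0].max() > 0      # events do occur above own p99
        b = baseline_maxima(m)
        assert suitable_years(m, b).all()


class TestCombineGcms:
    def test_majority_unsuitable(self):
        assert combine_gcms(np.array([True, True, True, False, False]))

    def test_all_suitable(self):
        assert not combine_gcms(np.zeros(5, dtype=bool))

    def test_minority_unsuitable_stays_suitable(self):
        assert not combine_gcms(np.array([True, True, False, False, False]))

    def test_even_model_count_rejected(self):
        with pytest.raises(ValueError):
            combine_gcms(np.zeros((4, 3), dtype=bool))

    def test_vectorised_over_cells(self):
        flags = np.array([[True, False], [True, False], [False, False]])
        out = combine_gcms(flags)
        assert out.tolist() == [True, False]
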