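"""Suitable-area accounting, extinction rule, change index, attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heatland.grid_ranges import FIVE_CLASSES, SpeciesRecord, build_grid
from heatland.landuse import FiveClassLayer
from heatland.exposure import (NoInitialHabitatError, apply_extinction_rule,
                               attribute_driver, build_trajectory,
                               exposure_fraction, percent_change, sa_2015,
                               suitable_area_series, suitable_area_year,
                               threshold_counts)

GRID = build_grid(2, 2, 24.125)
AREA = GRID.cell_area_km2


def _layer(per_cell_forest):
    frac = np.zeros((4, 5))
    frac[:, FIVE_CLASSES.index("forest")] = per_cell_forest
    return FiveClassLayer(year=2015, fractions=frac)


def _sp(cells=(0, 1, 2), prefs=("forest",)):
    return SpeciesRecord("sp", "mammal", "LC", frozenset(cells),
                         frozenset(prefs))


class TestSuitableArea:
    def test_all_cells_climate_suitable(self):
        layers = {2050: _layer([0.5, 0.2, 0.0, 0.9])}
        flags = {2050: {0: True, 1: True, 2: True}}
        sa = suitable_area_year(_sp(), layers, flags, 2050, GRID)
        assert sa == pytest.approx(0.7 * AREA)

    def test_unsuitable_cell_removed(self):
        layers = {2050: _layer([0.5, 0.2, 0.0, 0.9])}
        flags = {2050: {0: True, 1: False, 2: True}}
        sa = suitable_area_year(_sp(), layers, flags, 2050, GRID)
        assert sa == pytest.approx(0.5 * AREA)

    def test_zero_fractions(self):
        layers = {2050: _layer([0, 0, 0, 0])}
        flags = {2050: {0: True, 1: True, 2: True}}
        assert suitable_area_year(_sp(), layers, flags, 2050, GRID) == 0.0

    def test_before_climate_start_ignores_flags(self):
        layers = {2016: _layer([0.5, 0.2, 0.0, 0.9])}
        sa = suitable_area_year(_sp(), layers, None, 2016, GRID)
        assert sa == pytest.approx(0.7 * AREA)

    def test_landuse_only_ignores_flags(self):
        layers = {2050: _layer([0.5, 0.2, 0.0, 0.9])}
        flags = {2050: {0: False, 1: False, 2: False}}
        sa = suitable_area_year(_sp(), layers, flags, 2050, GRID,
                                driver_mode="landuse_only")
        assert sa == pytest.approx(0.7 * AREA)

    def test_climate_only_freezes_2015_weights(self):
        layers = {2015: _layer([0.6, 0.6, 0.6, 0.6]),
                  2050: _layer([0.1, 0.1, 0.1, 0.1])}
        flags = {2050: {0: True, 1: False, 2: True}}
        sa = suitable_area_year(_sp(), layers, flags, 2050, GRID,
                                driver_mode="climate_only")
        assert sa == pytest.approx(2 * 0.6 * AREA)

    def test_missing_layer_raises(self):
        with pytest.raises(KeyError):
            suitable_area_year(_sp(), {}, None, 2016, GRID)


class TestSa2015:
    def test_uniform_full_cover(self):
        layer = _layer([1.0, 1.0, 1.0, 1.0])
        sp = _sp(cells=(0, 1, 2, 3))
        assert sa_2015(sp, layer, GRID) == pytest.approx(4 * AREA)

    def test_fractional_cover_sums(self):
        layer = _layer([0.25, 0.75, 0, 0])
        assert sa_2015(_sp(cells=(0, 1)), layer, GRID) == pytest.approx(AREA)

    def test_no_preferred_habitat_gives_zero(self):
        layer = _layer([0.5, 0.5, 0.5, 0.5])
        sp = _sp(prefs=("urban",))
        assert sa_2015(sp, layer, GRID) == 0.0
        with pytest.raises(NoInitialHabitatError):
            percent_change(10.0, sa_2015(sp, layer, GRID))


class TestExtinctionRule:
    def test_no_recovery_after_zero(self):
        sa, yr = apply_extinction_rule(np.array([5.0, 0.0, 3.0]),
                                       np.array([2015, 2016, 2017]))
        assert sa.tolist() == [5.0, 0.0, 0.0]
        assert yr == 2016

    def test_untouched_when_always_positive(self):
        sa, yr = apply_extinction_rule(np.array([5.0, 4.0, 6.0]))
        assert sa.tolist() == [5.0, 4.0, 6.0]
        assert yr is None

    def test_zero_at_start_absorbs_everything(self):
        sa, yr = apply_extinction_rule(np.array([0.0, 1.0, 2.0]))
        assert sa.tolist() == [0.0, 0.0, 0.0]
        assert yr == 0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from([0.0, 0.5, 1.0, 3.0]), min_size=1,
                    max_size=30))
    def test_absorbing_and_idempotent(self, values):
        sa = np.array(values)
        once, yr1 = apply_extinction_rule(sa)
        twice, yr2 = apply_extinction_rule(once)
        np.testing.assert_array_equal(once, twice)
        assert yr1 == yr2
        if yr1 is not None:
            assert np.all(once[yr1:] == 0)
            np.testing.assert_array_equal(once[:yr1], sa[:yr1])


class TestPercentChange:
    @pytest.mark.parametrize("sa_y,base,pct,index", [
        (0.0, 10.0, -100.0, 0.0),
        (10.0, 10.0, 0.0, 100.0),
        (20.0, 10.0, 50.0, 150.0),
        (5.0, 10.0, -50.0, 50.0),
    ])
    def test_examples(self, sa_y, base, pct, index):
        got_pct, got_idx = percent_change(sa_y, base)
        assert got_pct == pytest.approx(pct)
        assert got_idx == pytest.approx(index)

    def test_invalid_baseline(self):
        with pytest.raises(NoInitialHabitatError):
            percent_change(1.0, 0.0)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(ratio=st.floats(0, 1e6, allow_nan=False))
    def test_bounds_over_ratio_sweep(self, ratio):
        pct, idx = percent_change(ratio * 10.0, 10.0)
        assert -100.0 <= pct < 100.0
        assert 0.0 <= idx < 200.0
        assert exposure_fraction(pct) == pytest.approx(max(0.0, -pct) / 100)


class TestTrajectory:
    def test_modes_differ_as_specified(self):
        years = np.arange(2015, 2020)
        hf = np.tile([[0.5, 0.5]], (5, 1)).astype(float)
        hf[3:, 1] = 0.1                       # land-use loss in cell 1
        ok = np.ones((5, 2), dtype=bool)
        ok[2:, 0] = False                     # climate loss in cell 0
        combined = suitable_area_series(hf, ok, 1.0, "combined")
        heat = suitable_area_series(hf, ok, 1.0, "climate_only")
        land = suitable_area_series(hf, ok, 1.0, "landuse_only")
        np.testing.assert_allclose(combined, [1.0, 1.0, 0.5, 0.1, 0.1])
        np.testing.assert_allclose(heat, [1.0, 1.0, 0.5, 0.5, 0.5])
        np.testing.assert_allclose(land, [1.0, 1.0, 1.0, 0.6, 0.6])
        assert np.all(combined <= np.minimum(heat, land) + 1e-12)

    def test_extinction_recorded(self):
        years = np.arange(2015, 2018)
        hf = np.array([[0.5], [0.0], [0.5]])
        ok = np.ones((3, 1), dtype=bool)
        traj = build_trajectory("sp", "SSP2-RCP4.5", "combined", years, hf,
                                ok, 1.0)
        assert traj.extinct_year == 2016
        assert traj.sa.tolist() == [0.5, 0.0, 0.0]


class TestAttribution:
    def test_heat_dominates(self):
        rec = attribute_driver("sp", "s", 0.9, 0.60, 0.20, 0.5)
        assert rec.cls == "heat"

    def test_landuse_dominates(self):
        rec = attribute_driver("sp", "s", 0.9, 0.20, 0.60, 0.5)
        assert rec.cls == "landuse"

    def test_combined_only(self):
        rec = attribute_driver("sp", "s", 0.55, 0.10, 0.10, 0.5)
        assert rec.cls == "combined_only"

    def test_both(self):
        rec = attribute_driver("sp", "s", 0.95, 0.9, 0.9, 0.5)
        assert rec.cls == "both"

    def test_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            attribute_driver("sp", "s", 0.4, 0.9, 0.9, 0.5)


class TestThresholdCounts:
    def test_counts_at_half_and_full(self):
        df = pd.DataFrame({"exposure_fraction": [0.4, 0.5, 1.0]})
        out = threshold_counts(df, thresholds=(0.5, 1.0))
        assert out.loc[out.threshold == 0.5, "n_exposed"].item() == 2
        assert out.loc[out.threshold == 1.0, "n_exposed"].item() == 1

    def test_grouped_percentages(self):
        df = pd.DataFrame({"exposure_fraction": [1.0, 0.0, 0.6, 0.7],
                           "taxon": ["bird", "bird", "frog", "frog"]})
        out = threshold_counts(df, thresholds=(0.5,), group_by="taxon")
        bird = out[out.group == "bird"].iloc[0]
        frog = out[out.group == "frog"].iloc[0]
        assert bird.n_exposed == 1 and bird.pct_exposed == pytest.approx(50)
        assert frog.n_exposed == 2 and frog.pct_exposed == pytest.approx(100)

    def test_empty_input_flagged(self):
        out = threshold_counts(pd.DataFrame({"exposure_fraction": []}),
                               thresholds=(0.5,))
        assert out.iloc[0].n_exposed == 0
        assert bool(out.iloc[0].undefined_pct)
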