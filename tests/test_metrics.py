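"""Thickness estimators, turnover, transit, healing, stability statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from corneasim.celltypes import BASAL, MEMB, STEM, SUPER, WING
from corneasim.metrics import (
    MetricsRecord, TurnoverTracker, binned_thickness_sd, healing_time,
    layer_transit_time, population_stability_stats, segment_super_positions,
    segment_top_positions, stability_day, thickness_com, turnover_time,
    wound_open_fraction,
)
from corneasim.potts import CellRegistry, LatticeState

from conftest import finalize, place_cell


def slab_state(sup_y=35, low_y=10, width=200, height=90):
    """Flat synthetic tissue: one-voxel basal and superficial slabs."""
    state = LatticeState.empty(width, height)
    state.tmap[low_y, :] = BASAL
    state.tmap[sup_y, :] = SUPER
    return state


class TestThicknessCom:
    def test_slab_distance(self):
        # super slab at y=35, basal at y=10: (35-10) voxels * 2 μm = 50 μm
        assert thickness_com(slab_state()) == pytest.approx(50.0)

    def test_same_height_zero(self):
        state = LatticeState.empty(40, 40)
        state.tmap[12, :20] = BASAL
        state.tmap[12, 20:] = SUPER
        assert thickness_com(state, x_window=(0, 40)) == pytest.approx(0.0)

    def test_missing_layer_is_nan(self):
        state = LatticeState.empty(40, 40)
        state.tmap[12, :] = BASAL
        assert math.isnan(thickness_com(state))

    def test_window_excludes_limbus(self):
        state = slab_state()
        state.tmap[60, :80] = SUPER    # a thick limbal lump, x < 80
        full = thickness_com(state, x_window=(0, 200))
        central = thickness_com(state)
        assert central == pytest.approx(50.0)
        assert full > central


class TestSegmentTops:
    def test_flat_fixture(self):
        state = LatticeState.empty(200, 90)
        state.tmap[:31, :] = BASAL    # top epithelial voxel at y = 30
        tops = segment_top_positions(state)
        assert len(tops) == 10
        assert all(t == pytest.approx(60.0) for t in tops)

    def test_step_fixture(self):
        state = LatticeState.empty(200, 90)
        state.tmap[:41, :100] = BASAL   # left: top y = 40 -> 80 μm
        state.tmap[:26, 100:] = BASAL   # right: top y = 25 -> 50 μm
        tops = segment_top_positions(state)
        assert all(t == pytest.approx(80.0) for t in tops[:5])
        assert all(t == pytest.approx(50.0) for t in tops[5:])

    def test_super_positions_average_the_layer(self):
        state = LatticeState.empty(200, 90)
        state.tmap[30:32, :] = SUPER    # centroid rows 30-31 -> 30.5 voxels
        vals = segment_super_positions(state)
        assert all(v == pytest.approx(61.0) for v in vals)

    def test_super_positions_nan_without_layer(self):
        state = LatticeState.empty(200, 90)
        state.tmap[30, :100] = SUPER    # right half has no superficial cells
        vals = segment_super_positions(state)
        assert all(not math.isnan(v) for v in vals[:5])
        assert all(math.isnan(v) for v in vals[5:])

    def test_bin_width_must_divide(self):
        state = LatticeState.empty(201, 30)
        with pytest.raises(ValueError):
            segment_top_positions(state)

    def test_agrees_with_com_on_flat_fixture(self):
        """The two estimators measure the same construct on a flat slab."""
        state = LatticeState.empty(200, 90)
        state.tmap[10, :] = MEMB
        state.tmap[11:13, :] = BASAL
        state.tmap[13:34, :] = WING
        state.tmap[34:36, :] = SUPER
        com = thickness_com(state)
        tops = segment_top_positions(state)
        bin_thick = np.mean(tops) - 10 * state.voxel_edge
        assert abs(com - bin_thick) / bin_thick < 0.20


class TestWoundOpen:
    def test_closed_surface(self):
        state = slab_state()
        assert wound_open_fraction(state) == 0.0

    def test_open_columns_counted(self):
        state = slab_state()
        state.tmap[35, 40:60] = WING   # 20 of 200 columns lose coverage
        assert wound_open_fraction(state) == pytest.approx(0.10)


class TestTurnover:
    def _tracker(self):
        state = LatticeState.empty(200, 90)
        cells = CellRegistry()
        limbal = [place_cell(state, cells, STEM, 12, 14, x, x + 2)
                  for x in range(2, 30, 4)]
        periph = [place_cell(state, cells, BASAL, 12, 14, x, x + 2)
                  for x in range(60, 180, 4)]
        finalize(state, cells)
        return TurnoverTracker(state, cells), cells, limbal, periph

    def test_immortal_population_never_turns_over(self):
        tracker, cells, _, _ = self._tracker()
        for day in range(1, 10):
            tracker.update(cells, day * 240)
        assert math.isnan(turnover_time(tracker, "limbal"))
        assert math.isnan(turnover_time(tracker, "peripheral"))

    def test_replacement_at_day_three(self):
        tracker, cells, limbal, periph = self._tracker()
        for day in range(1, 6):
            if day == 3:
                cells.alive[limbal] = 0
                cells.alive[periph] = 0
            tracker.update(cells, day * 240)
        assert turnover_time(tracker, "limbal") == pytest.approx(3.0)

    def test_regions_are_independent(self):
        tracker, cells, limbal, periph = self._tracker()
        for day in range(1, 6):
            if day == 2:
                cells.alive[periph] = 0   # only the peripheral census dies
            tracker.update(cells, day * 240)
        assert turnover_time(tracker, "peripheral") == pytest.approx(2.0)
        assert math.isnan(turnover_time(tracker, "limbal"))

    def test_substitution_fraction_monotone(self):
        tracker, cells, limbal, periph = self._tracker()
        rng = np.random.default_rng(0)
        prev = 0.0
        ids = np.concatenate([limbal, periph])
        for day in range(1, 15):
            kill = ids[rng.random(len(ids)) < 0.1]
            cells.alive[kill] = 0
            tracker.update(cells, day * 240)
            frac = tracker.substitution_fraction("peripheral")
            assert frac >= prev
            prev = frac


class TestTransit:
    def _log(self, rows):
        return pd.DataFrame(
            rows, columns=["mcs", "cell", "event", "old_type", "new_type",
                           "lifetime_mcs", "layers"])

    def test_single_trajectory(self):
        # born day 0, 4 layers, sloughed day 7 -> 7/4 = 1.75 days/layer
        log = self._log([(1680, 10, "slough", SUPER, -1, 1680, 4)])
        assert layer_transit_time(log) == pytest.approx(1.75)

    def test_mean_of_two(self):
        log = self._log([
            (1680, 10, "slough", SUPER, -1, 7 * 240, 4),
            (3360, 11, "slough", SUPER, -1, 14 * 240, 8),
        ])
        assert layer_transit_time(log) == pytest.approx(1.75)

    def test_empty_log_is_nan(self):
        assert math.isnan(layer_transit_time(self._log([])))
        # logs with no slough events are also undefined
        log = self._log([(100, 10, "divide", BASAL, BASAL, -1, -1)])
        assert math.isnan(layer_transit_time(log))


def _series(days, thickness, open_frac, counts=None):
    out = []
    for d, th, op in zip(days, thickness, open_frac):
        out.append(MetricsRecord(
            mcs=int(d * 240), day=d,
            counts=counts or {"STEM": 8, "BASAL": 20, "WING": 60, "SUPER": 50},
            thickness_com=th, bin_top=[50.0] * 10, bin_thickness=[30.0] * 10,
            wound_open_fraction=op, stratified=True))
    return out


class TestHealing:
    def test_no_injury_effect_is_zero_days(self):
        days = np.arange(0, 10, 0.5)
        s = _series(days, [50.0] * len(days), [0.0] * len(days))
        hd, rec = healing_time(s, injury_mcs=5 * 240)
        assert hd == 0.0 and rec == 0

    def test_closure_at_day_four(self):
        days = np.arange(0, 12, 0.5)
        th, op = [], []
        for d in days:
            if d < 5:
                th.append(50.0); op.append(0.0)
            elif d < 9:                      # injured at day 5, heals day 9
                th.append(30.0); op.append(0.4)
            else:
                th.append(50.0); op.append(0.0)
        hd, rec = healing_time(_series(days, th, op), injury_mcs=5 * 240)
        assert hd == pytest.approx(4.0)
        assert rec == 0

    def test_reopening_counts_recurrences(self):
        days = np.arange(0, 20, 0.5)
        th, op = [], []
        for d in days:
            if d < 5:
                th.append(50.0); op.append(0.0)
            else:                             # erodes periodically, never
                th.append(30.0)               # returns to the band
                op.append(0.3 if (int(d * 2) % 4 == 0) else 0.0)
        hd, rec = healing_time(_series(days, th, op), injury_mcs=5 * 240)
        assert math.isnan(hd)
        assert rec >= 1

    def test_series_short_of_injury_raises(self):
        s = _series([0.0, 1.0], [50.0, 50.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            healing_time(s, injury_mcs=10 * 240)


class TestStabilityStats:
    def test_constant_series_zero_sd(self):
        days = np.arange(0, 5, 0.5)
        s = _series(days, [50.0] * len(days), [0.0] * len(days))
        df = population_stability_stats(s, (0, 5 * 240))
        assert (df["sd"] == 0.0).all()

    def test_alternating_counts(self):
        rows = []
        for i, d in enumerate(np.arange(0, 4, 0.5)):
            rows.extend(_series([d], [50.0], [0.0],
                                counts={"STEM": 0, "BASAL": 0, "WING": 0,
                                        "SUPER": 10 if i % 2 == 0 else 12}))
        df = population_stability_stats(rows, (0, 4 * 240))
        assert df.loc["SUPER", "mean"] == pytest.approx(11.0)
        assert df.loc["SUPER", "sd"] == pytest.approx(1.0)

    def test_stability_detector_flat_series(self):
        days = np.arange(0, 10, 0.5)
        s = _series(days, [50.0] * len(days), [0.0] * len(days))
        assert stability_day(s) <= 3.5

    def test_binned_sd_constant_is_zero(self):
        days = np.arange(0, 5, 0.5)
        s = _series(days, [50.0] * len(days), [0.0] * len(days))
        assert binned_thickness_sd(s, (0, 5 * 240)) == 0.0
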