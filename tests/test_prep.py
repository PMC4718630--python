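"""Event collapsing, species filters, history building, period grouping
and detection-level classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wpimon as w
from wpimon.prep import period_slices

from conftest import make_history


def _events(times, point="P1", species="sp", site="S"):
    return pd.DataFrame({
        "site": site, "point": point, "species": species,
        "timestamp": pd.to_datetime(times),
    })


class TestCollapseEvents:
    def test_images_within_a_minute_merge_to_one_event(self):
        ev = _events(["2012-02-01 10:00:00", "2012-02-01 10:00:30"])
        assert len(w.collapse_events(ev)) == 1

    def test_empty_table_passes_through(self):
        ev = _events([])
        assert w.collapse_events(ev).empty

    def test_greedy_left_to_right_merge(self):
        base = pd.Timestamp("2012-02-01 10:00:00")
        ev = _events([base + pd.Timedelta(seconds=s)
                      for s in (0, 30, 61, 100, 200)])
        out = w.collapse_events(ev)
        secs = [(t - base).total_seconds() for t in out["timestamp"]]
        assert secs == [0, 61, 200]

    def test_exactly_one_minute_apart_stays_distinct(self):
        ev = _events(["2012-02-01 10:00:00", "2012-02-01 10:01:00"])
        assert len(w.collapse_events(ev)) == 2

    def test_groups_are_independent(self):
        a = _events(["2012-02-01 10:00:00", "2012-02-01 10:00:20"], point="P1")
        b = _events(["2012-02-01 10:00:10"], point="P2")
        out = w.collapse_events(pd.concat([a, b]))
        assert len(out) == 2

    def test_malformed_timestamp_raises_with_row(self):
        ev = pd.DataFrame({"site": "S", "point": "P1", "species": "sp",
                           "timestamp": ["2012-02-01 10:00:00", "not-a-date"]})
        with pytest.raises(ValueError, match="row"):
            w.collapse_events(ev)


class TestFilterSpecies:
    TRAITS = pd.DataFrame({
        "species": ["light", "ground", "arb"],
        "mass_g": [99.0, 100.0, 5000.0],
        "terrestrial": [True, True, False],
    })

    def test_mass_boundary(self):
        ev = _events(["2012-02-01 10:00:00"], species="ground")
        kept = w.filter_species(self.TRAITS, ev)
        assert "ground" in kept        # exactly 100 g is included
        assert "light" not in kept     # 99 g falls below the threshold

    @pytest.mark.parametrize("counts,expect", [((5, 5, 6), True),
                                               ((5, 4, 6), False)])
    def test_arboreal_needs_five_events_every_year(self, counts, expect):
        rows = []
        for yr, cnt in zip((2010, 2011, 2012), counts):
            for i in range(cnt):
                rows.append(f"{yr}-02-01 {8 + i}:00:00")
        ev = _events(rows, species="arb")
        kept = w.filter_species(self.TRAITS, ev)
        assert ("arb" in kept) is expect

    def test_unknown_species_excluded_with_warning(self):
        ev = _events(["2012-02-01 10:00:00"], species="mystery")
        with pytest.warns(UserWarning, match="mystery"):
            kept = w.filter_species(self.TRAITS, ev)
        assert "mystery" not in kept


class TestBuildHistory:
    DEP = pd.DataFrame({
        "point": ["P1", "P2", "P3"],
        "start_date": ["2012-02-01", "2012-02-03", "2012-02-05"],
        "end_date": ["2012-02-06", "2012-02-08", "2012-02-10"],
    })

    def test_matches_hand_built_matrix(self):
        ev = _events(["2012-02-03 09:00:00"], point="P1")
        mat, pids, t0 = w.build_history(ev, self.DEP, "sp", 2012)
        # window 2012-02-01..2012-02-10 (10 days)
        expect = np.full((3, 10), np.nan)
        expect[0, 0:6] = 0.0
        expect[1, 2:8] = 0.0
        expect[2, 4:10] = 0.0
        expect[0, 2] = 1.0
        np.testing.assert_array_equal(mat, expect)
        assert pids == ["P1", "P2", "P3"]

    def test_no_events_gives_zeros_on_active_days(self):
        mat, _, _ = w.build_history(_events([]), self.DEP, "sp", 2012)
        assert np.nansum(mat) == 0
        assert int(np.sum(~np.isnan(mat[0]))) == 6

    def test_event_at_unknown_point_is_integrity_error(self):
        ev = _events(["2012-02-03 09:00:00"], point="P9")
        with pytest.raises(ValueError, match="P9"):
            w.build_history(ev, self.DEP, "sp", 2012)

    def test_event_outside_window_is_integrity_error(self):
        ev = _events(["2012-02-09 09:00:00"], point="P1")  # P1 ended Feb 6
        with pytest.raises(ValueError, match="outside"):
            w.build_history(ev, self.DEP, "sp", 2012)


class TestGroupPeriods:
    def test_112_days_gives_7_and_8_day_periods(self):
        lengths = [s.stop - s.start for s in period_slices(112, 15)]
        assert sorted(set(lengths)) == [7, 8]
        assert sum(lengths) == 112
        # longer blocks come first
        assert lengths == sorted(lengths, reverse=True)

    def test_all_missing_row_stays_missing(self):
        day = np.full((1, 30), np.nan)
        out = w.group_periods(day, 15)
        assert np.isnan(out).all()

    def test_single_detection_day40_of_105_lands_in_period_6(self):
        day = np.zeros((1, 105))
        day[0, 39] = 1.0  # day 40, 1-based
        out = w.group_periods(day, 15)
        assert out[0, 5] == 1.0  # period 6, 1-based
        assert np.nansum(out) == 1.0

    def test_too_few_days_raises(self):
        with pytest.raises(ValueError):
            period_slices(10, 15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_grouping_never_creates_detections(self, seed):
        rng = np.random.default_rng(seed)
        J, D = int(rng.integers(1, 6)), int(rng.integers(15, 60))
        day = rng.choice([0.0, 1.0, np.nan], size=(J, D), p=[0.6, 0.2, 0.2])
        out = w.group_periods(day, 15)
        assert np.nansum(out) <= np.nansum(day)
        for j, sl in [(j, sl) for j in range(J)
                      for sl in period_slices(D, 15)]:
            block = day[j, sl]
            per = out[j, period_slices(D, 15).index(sl)]
            if np.isnan(block).all():
                assert np.isnan(per)
            else:
                assert per == float(np.nansum(block) > 0)


class TestClassifyCase:
    def test_zero_detections_is_case3(self):
        h = make_history(np.zeros((10, 2, 15)))
        c = w.classify_case(h)
        assert c.level == 3
        assert c.mean_detections_per_year == 0.0

    def test_rate_above_8pct_is_case1(self):
        # 60 points x 15 periods fully sampled, 80 detections/year
        vals = np.zeros((60, 2, 15))
        for t in range(2):
            flat = np.zeros(60 * 15)
            flat[:80] = 1.0
            vals[:, t, :] = flat.reshape(60, 15)
        c = w.classify_case(make_history(vals))
        assert c.level == 1
        assert c.annual_detection_rate == pytest.approx(80 / 900)

    def test_low_rate_enough_detections_is_case2(self):
        # 6 detections/year at rate well under 8%
        vals = np.zeros((60, 2, 15))
        vals[:6, :, 0] = 1.0
        c = w.classify_case(make_history(vals))
        assert c.level == 2
        assert c.mean_detections_per_year == 6.0

    def test_empty_history_raises(self):
        with pytest.raises(ValueError):
            w.classify_case(make_history(np.full((3, 2, 15), np.nan)))

    def test_invariant_to_point_permutation(self, rng):
        vals = rng.choice([0.0, 1.0, np.nan], size=(20, 3, 15),
                          p=[0.7, 0.1, 0.2])
        c1 = w.classify_case(make_history(vals))
        c2 = w.classify_case(make_history(vals[rng.permutation(20)]))
        assert (c1.level, c1.annual_detection_rate) == \
            (c2.level, c2.annual_detection_rate)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_case_partition_is_exhaustive_and_exclusive(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.choice([0.0, 1.0, np.nan], size=(8, 3, 15),
                          p=[0.55, 0.25, 0.2])
        if np.isnan(vals).all():
            vals[0, 0, 0] = 0.0
        c = w.classify_case(make_history(vals))
        assert c.level in (1, 2, 3)
        if c.annual_detection_rate > 0.08:
            assert c.level == 1
        elif c.mean_detections_per_year < 5:
            assert c.level == 3
        else:
            assert c.level == 2


def test_prepare_populations_end_to_end(default_bundle):
    _, b = default_bundle
    hists = w.prepare_populations(b["events"], b["deployments"], b["traits"],
                                  site="SIM")
    h = hists["species_01"]
    assert h.values.shape == (60, 5, 15)
    # staggered 30-day deployments sample ~4-5 of the 15 periods
    _, n = h.annual_summaries()
    assert 3 <= n[n > 0].min() and n.max() <= 6
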