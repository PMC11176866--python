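"""Ectopic filtering, night segmentation and time-domain HRV statistics."""

from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvidh.time_domain import (HRVParams, RRISeries, aggregate_night,
                                filter_ectopic, night_segments, time_domain)
from tests.conftest import MIDNIGHT, make_segment


class TestFilterEctopic:
    def test_20_percent_rule_uses_last_accepted_reference(self):
        # 1000 deviates 23.5% from 810 -> flagged; 805 compared against 810
        # (the last accepted), not against 1000
        s = RRISeries.from_intervals([800, 810, 1000, 805], MIDNIGHT)
        out = filter_ectopic(s)
        assert out.excluded.tolist() == [False, False, True, False]
        assert out.exclusion_reason[2] == "ectopic"

    def test_constant_series_nothing_flagged(self):
        out = filter_ectopic(RRISeries.from_intervals([1000] * 100, MIDNIGHT))
        assert not out.excluded.any()

    def test_first_interval_never_flagged(self):
        out = filter_ectopic(RRISeries.from_intervals([1500, 1000, 1000], MIDNIGHT))
        assert not out.excluded[0]

    def test_flag_only_contract_preserves_data(self):
        s = RRISeries.from_intervals([800, 810, 1000, 805], MIDNIGHT)
        out = filter_ectopic(s)
        np.testing.assert_array_equal(out.intervals, s.intervals)
        assert out.excluded.sum() + out.n_accepted == len(s)

    def test_isolated_ectopics_all_recovered(self):
        # ground truth at scale 1.5 with >=2 normal beats between ectopics
        rng = np.random.default_rng(0)
        iv = 800 + rng.normal(0, 5, 300)
        truth = np.zeros(300, dtype=bool)
        truth[10::30] = True
        iv[truth] *= 1.5
        s = RRISeries.from_intervals(iv, MIDNIGHT)
        out = filter_ectopic(s)
        assert out.excluded[truth].all()          # sensitivity 100 %

    def test_short_series_warns_and_returns_unchanged(self):
        s = RRISeries.from_intervals([900], MIDNIGHT)
        with pytest.warns(UserWarning):
            out = filter_ectopic(s)
        assert not out.excluded.any()

    def test_corrupt_start_reanchors_instead_of_cascading(self):
        # ectopic first interval poisons the reference; the filter must
        # re-anchor after a bounded run rather than flag the whole recording
        iv = [1200.0] + [800.0] * 200
        out = filter_ectopic(RRISeries.from_intervals(iv, MIDNIGHT))
        assert out.excluded.mean() < 0.05


class TestNightSegments:
    def _series(self, start, hours, rri_ms=1000.0):
        n = int(hours * 3600 * 1000 / rri_ms)
        return RRISeries.from_intervals([rri_ms] * n, start)

    def test_four_hours_from_midnight_gives_48_segments(self):
        res = night_segments(self._series(MIDNIGHT, 4))
        assert res.status == "ok"
        assert len(res.segments) == 48

    def test_partial_night_coverage(self):
        res = night_segments(self._series(datetime(2022, 1, 1, 23, 0), 3))
        assert len(res.segments) == 24        # 00:00-02:00 only

    def test_daytime_recording_has_no_night_coverage(self):
        res = night_segments(self._series(datetime(2022, 1, 1, 10, 0), 1))
        assert res.segments == []
        assert res.status == "no_night_coverage"

    def test_segments_are_disjoint_and_clock_aligned(self):
        res = night_segments(self._series(MIDNIGHT, 4))
        idx = np.concatenate([s.indices for s in res.segments])
        assert len(idx) == len(set(idx))      # disjoint
        for seg in res.segments:
            assert seg.window_start.second == 0
            assert seg.window_start.minute % 5 == 0
            assert seg.duration_s == 300.0

    def test_sparse_segment_dropped_and_counted(self):
        # carve most beats out of one 5-min window via artefact flags
        s = self._series(MIDNIGHT, 1)
        excluded = np.zeros(len(s), dtype=bool)
        excluded[600:890] = True              # most of the 00:10-00:15 window
        s = RRISeries.from_intervals([1000.0] * len(s), MIDNIGHT, excluded=excluded)
        res = night_segments(s)
        assert len(res.segments) == 11
        assert res.n_dropped_incomplete == 1


class TestTimeDomain:
    def test_constant_series_zero_variability(self):
        p = time_domain(make_segment([1000.0] * 300))
        assert p.mean_hr == pytest.approx(60.0)
        assert p.sdnn == 0 and p.rmssd == 0 and p.nn50 == 0 and p.pnn50 == 0

    def test_alternating_series_closed_form(self):
        # two-value alternation: population SD = half the gap, every
        # successive difference = the gap
        p = time_domain(make_segment([1000.0, 940.0] * 150))
        assert p.sdnn == pytest.approx(30.0)
        assert p.rmssd == pytest.approx(60.0)
        assert p.nn50 == 299
        assert p.pnn50 == pytest.approx(100 * 299 / 300)

    def test_nn50_denominator_is_interval_count(self):
        p = time_domain(make_segment([900.0, 1000.0, 1060.0, 1050.0]))
        assert p.nn50 == 2                     # diffs 100, 60, 10
        assert p.pnn50 == pytest.approx(50.0)  # 2 of 4 intervals

    def test_exclusion_breaks_successive_difference_chain(self):
        # excluding the middle interval removes both pairs that touch it
        excluded = np.array([False, True, False, False])
        p = time_domain(make_segment([900.0, 1500.0, 1060.0, 1050.0],
                                     excluded=excluded))
        assert p.nn50 == 0                     # only pair left: |1050-1060|=10

    def test_all_excluded_errors(self):
        with pytest.raises(ValueError):
            time_domain(make_segment([1000.0] * 5,
                                     excluded=np.ones(5, dtype=bool)))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=300, max_value=2000), min_size=2,
                    max_size=400))
    def test_statistics_bounds_on_random_series(self, intervals):
        p = time_domain(make_segment(intervals))
        assert p.sdnn >= 0 and p.rmssd >= 0
        assert 0 <= p.pnn50 <= 100
        assert p.mean_hr > 0


class TestAggregateNight:
    def test_single_segment_is_identity(self):
        seg = HRVParams(mean_hr=60, sdnn=20, rmssd=15, nn50=4, pnn50=2,
                        tp=400, vlf=200, lf=120, hf=80, lf_hf_ratio=1.5)
        out = aggregate_night([seg])
        assert out.as_dict() == seg.as_dict()
        assert out.n_segments_averaged == 1

    def test_fields_are_arithmetic_means(self):
        a = HRVParams(tp=400, lf_hf_ratio=1.0)
        b = HRVParams(tp=600, lf_hf_ratio=3.0)
        out = aggregate_night([a, b])
        assert out.tp == pytest.approx(500.0)

    def test_ratio_is_mean_of_ratios_not_pooled(self):
        # powers 800/100 and 100/200: mean of ratios (8 + 0.5)/2 = 4.25,
        # pooled 900/300 = 3.0 — the two conventions separate here
        a = HRVParams(lf=800, hf=100, lf_hf_ratio=8.0)
        b = HRVParams(lf=100, hf=200, lf_hf_ratio=0.5)
        out = aggregate_night([a, b])
        assert out.lf_hf_ratio == pytest.approx(4.25)

    def test_missing_ratios_skipped(self):
        a = HRVParams(lf_hf_ratio=2.0)
        b = HRVParams(lf_hf_ratio=None)
        assert aggregate_night([a, b]).lf_hf_ratio == pytest.approx(2.0)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            aggregate_night([])
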