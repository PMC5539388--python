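"""Instrument scoring: EMA midpoints, BRFSS products, IPAQ conversion, screen time."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paconcord import (
    BrfssResponse,
    EmaDiaryResponse,
    IpaqResponse,
    ScreenTimeResponse,
    bin_ema_minutes,
    ema_midpoints,
    score_brfss,
    score_ema_category,
    score_ema_week,
    score_ipaq,
    score_screen_time,
)


class TestScoreEmaCategory:
    def test_worked_example_20_to_29_minutes(self):
        # the 20-29 min response option scores the mean of its span
        assert score_ema_category(3) == pytest.approx(24.5)

    @pytest.mark.parametrize("category,minutes", [
        (1, 4.5), (2, 14.5), (4, 34.5), (7, 64.5), (8, 70.0),
    ])
    def test_default_midpoint_table(self, category, minutes):
        assert score_ema_category(category) == pytest.approx(minutes)

    @pytest.mark.parametrize("bad", [0, 9, -1])
    def test_out_of_range_category(self, bad):
        with pytest.raises(ValueError):
            score_ema_category(bad)

    def test_custom_top_category(self):
        table = ema_midpoints(top_category_minutes=90.0)
        assert score_ema_category(8, table) == pytest.approx(90.0)

    @given(st.integers(min_value=0, max_value=69))
    @settings(derandomize=True, max_examples=100)
    def test_midpoint_within_half_bin_of_input(self, minutes):
        # whole reported minutes below the top-coded category land within
        # half a bin width of their midpoint score
        scored = score_ema_category(bin_ema_minutes(minutes))
        assert abs(scored - minutes) <= 4.5


class TestScoreEmaWeek:
    def mk(self, day, mod=None, vig=None):
        return EmaDiaryResponse("P1", day, mod, vig)

    def test_full_week(self):
        resp = [self.mk(d, 3, 1) for d in range(1, 8)]
        est = score_ema_week(resp)
        assert est.moderate_min_wk == pytest.approx(7 * 24.5)
        assert est.vigorous_min_wk == pytest.approx(7 * 4.5)
        assert est.mvpa_min_wk == pytest.approx(203.0)
        assert est.n_days_used == 7

    def test_no_answered_days_is_missing(self):
        assert score_ema_week([]) is None
        assert score_ema_week([self.mk(1), self.mk(2)]) is None

    def test_single_day_no_rescaling(self):
        est = score_ema_week([self.mk(4, 8, 8)])
        assert est.mvpa_min_wk == pytest.approx(140.0)
        assert est.n_days_used == 1

    def test_optional_rescaling_to_seven_days(self):
        est = score_ema_week([self.mk(1, 3, 1)], rescale_to_7_days=True)
        assert est.moderate_min_wk == pytest.approx(7 * 24.5)

    def test_duplicate_day_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            score_ema_week([self.mk(2, 3, 1), self.mk(2, 4, 1)])

    def test_bounded_by_top_category(self):
        resp = [self.mk(d, 8, 8) for d in range(1, 8)]
        est = score_ema_week(resp)
        assert est.moderate_min_wk <= 7 * 70
        assert est.vigorous_min_wk <= 7 * 70


class TestScoreBrfss:
    def test_duration_times_frequency(self):
        est = score_brfss(BrfssResponse(30, 5, 20, 3))
        assert (est.moderate_min_wk, est.vigorous_min_wk, est.mvpa_min_wk) == \
            (pytest.approx(150), pytest.approx(60), pytest.approx(210))

    def test_all_zero(self):
        est = score_brfss(BrfssResponse(0, 0, 0, 0))
        assert est.mvpa_min_wk == 0

    def test_missing_component_propagates(self):
        est = score_brfss(BrfssResponse(None, None, 20, 3))
        assert est.moderate_min_wk is None
        assert est.vigorous_min_wk == pytest.approx(60)
        assert est.mvpa_min_wk is None

    def test_times_per_week_may_exceed_seven(self):
        est = score_brfss(BrfssResponse(30, 10, 0, 0))
        assert est.moderate_min_wk == pytest.approx(300)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            BrfssResponse(-5, 3, 0, 0)


class TestScoreIpaq:
    def test_occupational_vigorous_conversion(self):
        est = score_ipaq(IpaqResponse(occ_vigorous_days=2, occ_vigorous_hours=1))
        assert est.vigorous_min_wk == pytest.approx(120)
        assert est.moderate_min_wk == 0
        assert est.mvpa_min_wk == pytest.approx(120)

    def test_transport_bicycling_counts_as_moderate(self):
        est = score_ipaq(IpaqResponse(transport_bicycling_days=5,
                                      transport_bicycling_hours=0.5))
        assert est.moderate_min_wk == pytest.approx(150)
        assert est.vigorous_min_wk == 0

    def test_walking_items_count_as_moderate(self):
        est = score_ipaq(IpaqResponse(occ_walking_days=3, occ_walking_hours=1,
                                      transport_walking_days=2,
                                      transport_walking_hours=0.5))
        assert est.moderate_min_wk == pytest.approx(180 + 60)

    def test_all_zero(self):
        est = score_ipaq(IpaqResponse())
        assert est.mvpa_min_wk == 0
        assert est.sedentary_min_wk is None

    def test_sitting_weekday_weekend_weighting(self):
        est = score_ipaq(IpaqResponse(sitting_hours_weekday=8,
                                      sitting_hours_weekend=1))
        # (5*8 + 2*1)/7 hours/day * 60 * 7 = (40+2)*60
        assert est.sedentary_min_wk == pytest.approx(42 * 60)

    def test_days_over_seven_rejected(self):
        with pytest.raises(ValueError, match="days"):
            IpaqResponse(occ_moderate_days=8, occ_moderate_hours=1)


class TestScoreScreenTime:
    def test_weekday_weekend_weighting(self):
        est = score_screen_time(ScreenTimeResponse(2, 4, 1, 1))
        # (3 h x 5 days + 5 h x 2 days) x 60 = 1500 sedentary min/week
        assert est.sedentary_min_wk == pytest.approx(1500)
        assert est.moderate_min_wk is None

    def test_all_zero(self):
        assert score_screen_time(ScreenTimeResponse()).sedentary_min_wk == 0

    def test_impossible_total_rejected_by_default(self):
        with pytest.raises(ValueError, match="impossible"):
            score_screen_time(ScreenTimeResponse(24, 24, 24, 24))

    def test_impossible_total_capped_on_request(self):
        est = score_screen_time(ScreenTimeResponse(24, 24, 24, 24),
                                on_impossible="cap")
        assert est.sedentary_min_wk == pytest.approx(10080)

    def test_hours_over_24_rejected(self):
        with pytest.raises(ValueError):
            ScreenTimeResponse(tv_weekday_h=25)


class TestScoredInvariants:
    @given(
        st.floats(0, 300), st.floats(0, 20), st.floats(0, 300), st.floats(0, 20)
    )
    @settings(derandomize=True, max_examples=100)
    def test_brfss_nonnegative_and_additive(self, md, mt, vd, vt):
        est = score_brfss(BrfssResponse(md, mt, vd, vt))
        assert est.moderate_min_wk >= 0 and est.vigorous_min_wk >= 0
        assert est.mvpa_min_wk == pytest.approx(est.moderate_min_wk
                                                + est.vigorous_min_wk)

    @given(st.lists(st.tuples(st.integers(1, 8), st.integers(1, 8)),
                    min_size=1, max_size=7))
    @settings(derandomize=True, max_examples=100)
    def test_ema_week_additive(self, cats):
        resp = [EmaDiaryResponse("P1", i + 1, m, v)
                for i, (m, v) in enumerate(cats)]
        est = score_ema_week(resp)
        assert est.mvpa_min_wk == pytest.approx(est.moderate_min_wk
                                                + est.vigorous_min_wk)
        assert est.moderate_min_wk <= 7 * 70
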