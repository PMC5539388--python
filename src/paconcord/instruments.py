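"""Scoring of the four self-report instruments into weekly estimates.

Each instrument is reduced to the common currency of minutes/week by
intensity:

* **EMA daily diary** — each day's moderate and vigorous category (1..8) is
  scored as its bin midpoint (24.5 min for the 20-29 category; 70 for the
  open-ended top category) and summed across answered days.  Missing days are
  not imputed or rescaled by default.
* **BRFSS leisure-time items** — minutes/week = duration (min/day) x
  frequency (times/week), per intensity.
* **IPAQ occupational/transport items** — per item, minutes/week =
  days/week x hours/day x 60; walking for work, walking for transport and
  bicycling for transport count as moderate, occupational vigorous as
  vigorous.  Sitting items give sedentary minutes/week via a 5-weekday /
  2-weekend-day average.
* **Screen time** — sedentary minutes/week from TV + computer hours/day,
  weekdays weighted 5 and weekend days 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .accelerometry import WeeklyEstimate
from .ema import EMA_N_CATEGORIES, EMA_TOP_CATEGORY_MINUTES, ema_midpoints

MINUTES_PER_WEEK = 7 * 1440


@dataclass(frozen=True)
class EmaDiaryResponse:
    participant_id: str
    day_index: int
    moderate_category: Optional[int] = None
    vigorous_category: Optional[int] = None

    def __post_init__(self) -> None:
        if not (1 <= self.day_index <= 7):
            raise ValueError(f"day_index must be 1..7, got {self.day_index}")
        for name in ("moderate_category", "vigorous_category"):
            c = getattr(self, name)
            if c is not None and not (1 <= c <= EMA_N_CATEGORIES):
                raise ValueError(f"{name} must be 1..{EMA_N_CATEGORIES}, got {c}")


@dataclass(frozen=True)
class BrfssResponse:
    moderate_min_per_day: Optional[float] = None
    moderate_times_per_week: Optional[float] = None
    vigorous_min_per_day: Optional[float] = None
    vigorous_times_per_week: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("moderate_min_per_day", "moderate_times_per_week",
                     "vigorous_min_per_day", "vigorous_times_per_week"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class IpaqResponse:
    """Five activity items (days/week, hours/day) plus two sitting items."""

    occ_vigorous_days: float = 0.0
    occ_vigorous_hours: float = 0.0
    occ_moderate_days: float = 0.0
    occ_moderate_hours: float = 0.0
    occ_walking_days: float = 0.0
    occ_walking_hours: float = 0.0
    transport_walking_days: float = 0.0
    transport_walking_hours: float = 0.0
    transport_bicycling_days: float = 0.0
    transport_bicycling_hours: float = 0.0
    sitting_hours_weekday: Optional[float] = None
    sitting_hours_weekend: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("occ_vigorous", "occ_moderate", "occ_walking",
                     "transport_walking", "transport_bicycling"):
            days = getattr(self, f"{name}_days")
            hours = getattr(self, f"{name}_hours")
            if not (0 <= days <= 7):
                raise ValueError(f"{name}_days must be 0..7, got {days!r}")
            if not (math.isfinite(hours) and hours >= 0):
                raise ValueError(f"{name}_hours must be finite and >= 0, got {hours!r}")
        for name in ("sitting_hours_weekday", "sitting_hours_weekend"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 24):
                raise ValueError(f"{name} must lie in [0, 24], got {v!r}")


@dataclass(frozen=True)
class ScreenTimeResponse:
    """TV and computer hours/day by day type (the 8 items collapse to these)."""

    tv_weekday_h: float = 0.0
    tv_weekend_h: float = 0.0
    computer_weekday_h: float = 0.0
    computer_weekend_h: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tv_weekday_h", "tv_weekend_h",
                     "computer_weekday_h", "computer_weekend_h"):
            v = getattr(self, name)
            if not (0 <= v <= 24):
                raise ValueError(f"{name} must lie in [0, 24] hours, got {v!r}")


def score_ema_category(
    category: int,
    midpoints: Sequence[float] | None = None,
) -> float:
    """Minutes assigned to one diary category: the mean value of its bin.

    With the default table, category 3 (20-29 min) scores 24.5 and the
    open-ended category 8 scores 70.
    """
    if midpoints is None:
        midpoints = ema_midpoints()
    if len(midpoints) != EMA_N_CATEGORIES:
        raise ValueError(f"midpoint table must have {EMA_N_CATEGORIES} entries")
    if not (1 <= category <= EMA_N_CATEGORIES):
        raise ValueError(f"category must be 1..{EMA_N_CATEGORIES}, got {category!r}")
    return float(midpoints[category - 1])


def score_ema_week(
    responses: Iterable[EmaDiaryResponse],
    midpoints: Sequence[float] | None = None,
    rescale_to_7_days: bool = False,
) -> Optional[WeeklyEstimate]:
    """Sum midpoint-scored categories across answered days into minutes/week.

    Days without a diary contribute nothing (no imputation); with
    ``rescale_to_7_days`` the per-answered-day mean is rescaled to 7 days
    instead.  A participant with no answered day yields None.
    """
    responses = list(responses)
    seen = [r.day_index for r in responses]
    if len(seen) != len(set(seen)):
        raise ValueError(f"duplicate day_index in EMA responses: {sorted(seen)}")
    answered = [r for r in responses
                if r.moderate_category is not None or r.vigorous_category is not None]
    if not answered:
        return None
    mod = sum(score_ema_category(r.moderate_category, midpoints)
              for r in answered if r.moderate_category is not None)
    vig = sum(score_ema_category(r.vigorous_category, midpoints)
              for r in answered if r.vigorous_category is not None)
    n = len(answered)
    if rescale_to_7_days:
        mod, vig = mod * 7.0 / n, vig * 7.0 / n
    return WeeklyEstimate(
        instrument="ema",
        moderate_min_wk=mod,
        vigorous_min_wk=vig,
        mvpa_min_wk=mod + vig,
        n_days_used=n,
    )


def score_brfss(r: BrfssResponse) -> WeeklyEstimate:
    """Duration x frequency per intensity; a missing component propagates."""
    def product(minutes, times):
        if minutes is None or times is None:
            return None
        return float(minutes) * float(times)

    mod = product(r.moderate_min_per_day, r.moderate_times_per_week)
    vig = product(r.vigorous_min_per_day, r.vigorous_times_per_week)
    mvpa = mod + vig if (mod is not None and vig is not None) else None
    return WeeklyEstimate(instrument="brfss", moderate_min_wk=mod,
                          vigorous_min_wk=vig, mvpa_min_wk=mvpa)


def score_ipaq(r: IpaqResponse, sitting_weekday_weight: float = 5.0) -> WeeklyEstimate:
    """days x hours x 60 per item; walking/bicycling items count as moderate.

    Sedentary minutes/week use the day-type-weighted mean of the two sitting
    items ((5 x weekday + 2 x weekend) / 7 by default) times 60 x 7.
    """
    def item(name):
        return getattr(r, f"{name}_days") * getattr(r, f"{name}_hours") * 60.0

    vig = item("occ_vigorous")
    mod = (item("occ_moderate") + item("occ_walking")
           + item("transport_walking") + item("transport_bicycling"))
    sed = None
    if r.sitting_hours_weekday is not None and r.sitting_hours_weekend is not None:
        w = sitting_weekday_weight
        daily = (w * r.sitting_hours_weekday + (7 - w) * r.sitting_hours_weekend) / 7.0
        sed = daily * 60.0 * 7.0
    return WeeklyEstimate(instrument="ipaq", sedentary_min_wk=sed,
                          moderate_min_wk=mod, vigorous_min_wk=vig,
                          mvpa_min_wk=mod + vig)


def score_screen_time(
    r: ScreenTimeResponse,
    on_impossible: str = "error",
) -> WeeklyEstimate:
    """Sedentary minutes/week from TV+computer hours (5 weekdays, 2 weekend days).

    Combined totals exceeding 24 h on a day type (or a week) are impossible
    responses: rejected by default, truncated with ``on_impossible='cap'``.
    """
    weekday_h = r.tv_weekday_h + r.computer_weekday_h
    weekend_h = r.tv_weekend_h + r.computer_weekend_h
    sed = (weekday_h * 5 + weekend_h * 2) * 60.0
    if weekday_h > 24 or weekend_h > 24 or sed > MINUTES_PER_WEEK:
        if on_impossible == "cap":
            sed = min(sed, float(MINUTES_PER_WEEK))
        else:
            raise ValueError(
                f"impossible screen-time response: {weekday_h} h weekday + "
                f"{weekend_h} h weekend day exceeds the day/week length"
            )
    return WeeklyEstimate(instrument="screen_time", sedentary_min_wk=sed)


def _tidy_rows(pid: str, est: Optional[WeeklyEstimate]) -> list[tuple]:
    if est is None:
        return []
    return [(pid, est.instrument, intensity, est.get(intensity))
            for intensity in ("sedentary", "moderate", "vigorous", "mvpa")
            if est.get(intensity) is not None]


def score_cohort(
    ema: pd.DataFrame,
    brfss: pd.DataFrame,
    ipaq: pd.DataFrame,
    screen_time: pd.DataFrame,
    midpoints: Sequence[float] | None = None,
    rescale_to_7_days: bool = False,
) -> pd.DataFrame:
    """Score whole response tables into the tidy estimates frame.

    Input frames follow the dialects in docs/data_dictionary.md; the result
    has one row per (participant_id, instrument, intensity) with
    ``minutes_per_week``.
    """
    rows: list[tuple] = []
    for pid, grp in ema.groupby("participant_id", sort=True):
        resp = [
            EmaDiaryResponse(
                str(pid), int(r.day),
                None if pd.isna(r.moderate_category) else int(r.moderate_category),
                None if pd.isna(r.vigorous_category) else int(r.vigorous_category),
            )
            for r in grp.itertuples()
        ]
        rows += _tidy_rows(str(pid), score_ema_week(resp, midpoints, rescale_to_7_days))
    for r in brfss.itertuples():
        resp = BrfssResponse(
            None if pd.isna(r.moderate_min_per_day) else float(r.moderate_min_per_day),
            None if pd.isna(r.moderate_times_per_week) else float(r.moderate_times_per_week),
            None if pd.isna(r.vigorous_min_per_day) else float(r.vigorous_min_per_day),
            None if pd.isna(r.vigorous_times_per_week) else float(r.vigorous_times_per_week),
        )
        rows += _tidy_rows(str(r.participant_id), score_brfss(resp))
    for r in ipaq.itertuples():
        resp = IpaqResponse(
            r.occ_vigorous_days, r.occ_vigorous_hours,
            r.occ_moderate_days, r.occ_moderate_hours,
            r.occ_walking_days, r.occ_walking_hours,
            r.transport_walking_days, r.transport_walking_hours,
            r.transport_bicycling_days, r.transport_bicycling_hours,
            None if pd.isna(r.sitting_hours_weekday) else float(r.sitting_hours_weekday),
            None if pd.isna(r.sitting_hours_weekend) else float(r.sitting_hours_weekend),
        )
        rows += _tidy_rows(str(r.participant_id), score_ipaq(resp))
    for r in screen_time.itertuples():
        resp = ScreenTimeResponse(r.tv_weekday_h, r.tv_weekend_h,
                                  r.computer_weekday_h, r.computer_weekend_h)
        rows += _tidy_rows(str(r.participant_id), score_screen_time(resp))
    return pd.DataFrame(
        rows, columns=["participant_id", "instrument", "intensity", "minutes_per_week"])
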