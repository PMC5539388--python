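"""Minute-epoch accelerometer processing.

Turns per-day vectors of 1440 activity counts (counts per 60-s epoch) into
wear-time-screened daily and weekly intensity summaries:

1. Nonwear detection: a nonwear period is >=60 consecutive minutes of zero
   counts, allowing interruptions of at most 2 consecutive epochs with counts
   between 1 and 100; any epoch above 100 counts, or a third consecutive
   nonzero epoch, terminates the period.  Wear time is 24 h minus nonwear.
2. Cut-point classification of worn epochs into sedentary / light / moderate /
   vigorous intensity (Freedson adult thresholds by default).
3. A day is valid with >=10 h of wear; participants need >=4 valid days for a
   weekly summary, computed as the mean over valid days scaled to 7 days.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
#: minimum wear minutes for a day to count toward weekly summaries (10 h)
DEFAULT_MIN_WEAR_MINUTES = 600
#: minimum number of valid days for a weekly accelerometer estimate
DEFAULT_MIN_VALID_DAYS = 4

INSTRUMENTS = ("accelerometer", "ema", "brfss", "ipaq", "screen_time")
INTENSITIES = ("sedentary", "moderate", "vigorous", "mvpa")


@dataclass(frozen=True)
class CutPoints:
    """Counts-per-minute thresholds separating intensity bands.

    An epoch is sedentary if counts <= ``sedentary_max``, light if
    <= ``light_max``, moderate if <= ``moderate_max``, else vigorous.
    Defaults are the standard adult Freedson thresholds.
    """

    sedentary_max: int = 99
    light_max: int = 1951
    moderate_max: int = 5724

    def __post_init__(self) -> None:
        if not (0 <= self.sedentary_max < self.light_max < self.moderate_max):
            raise ValueError(
                "cut points must satisfy 0 <= sedentary_max < light_max < moderate_max, "
                f"got {self}"
            )


@dataclass(frozen=True)
class EpochDay:
    """One participant-day of 1440 non-negative integer minute counts."""

    participant_id: str
    date: _dt.date
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (MINUTES_PER_DAY,):
            raise ValueError(
                f"counts must have length {MINUTES_PER_DAY}, got shape {c.shape}"
            )
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(np.equal(np.mod(c, 1), 0)):
                raise ValueError("counts must be integer-valued")
            c = c.astype(np.int64)
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class WearMask:
    """Boolean wear flags (True = worn) for one EpochDay, minute by minute."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.flags, dtype=bool)
        if f.shape != (MINUTES_PER_DAY,):
            raise ValueError(f"flags must have length {MINUTES_PER_DAY}")
        object.__setattr__(self, "flags", f)

    @property
    def wear_minutes(self) -> int:
        return int(self.flags.sum())


@dataclass(frozen=True)
class DailySummary:
    participant_id: str
    date: _dt.date
    wear_min: int
    sedentary_min: int
    light_min: int
    moderate_min: int
    vigorous_min: int
    valid: bool


@dataclass(frozen=True)
class WeeklyEstimate:
    """Minutes/week by intensity from one instrument — the common currency.

    Any field may be None (missing).  ``mvpa_min_wk`` is the sum of moderate
    and vigorous whenever both are present.
    """

    instrument: str
    sedentary_min_wk: Optional[float] = None
    moderate_min_wk: Optional[float] = None
    vigorous_min_wk: Optional[float] = None
    mvpa_min_wk: Optional[float] = None
    n_days_used: int = 0

    def __post_init__(self) -> None:
        if self.instrument not in INSTRUMENTS:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        for name in ("sedentary_min_wk", "moderate_min_wk", "vigorous_min_wk",
                     "mvpa_min_wk"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def get(self, intensity: str) -> Optional[float]:
        return {
            "sedentary": self.sedentary_min_wk,
            "moderate": self.moderate_min_wk,
            "vigorous": self.vigorous_min_wk,
            "mvpa": self.mvpa_min_wk,
        }[intensity]


def _runs(mask: np.ndarray) -> np.ndarray:
    """Half-open [start, end) spans of each maximal True run, as an (k, 2) array."""
    m = np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], m, [False])).astype(np.int8)))
    return edges.reshape(-1, 2)


def nonwear_mask(
    counts: np.ndarray,
    zero_run_min: int = 60,
    allowance_max_epochs: int = 2,
    allowance_cpm_max: int = 100,
) -> np.ndarray:
    """Boolean nonwear flags for a vector of minute counts.

    A minute is nonwear iff it lies in a maximal window of length
    >= ``zero_run_min`` consisting of zero-count epochs, with interior
    interruptions of at most ``allowance_max_epochs`` consecutive epochs each
    having counts in (0, ``allowance_cpm_max``].  An epoch above the allowance
    ceiling, or a longer run of nonzero epochs, terminates the window; the
    trailing interruption epochs of a terminated window count as wear.
    """
    c = np.asarray(counts)
    zero = c == 0
    allow = (c > 0) & (c <= allowance_cpm_max)
    # epochs that can never sit inside a nonwear window: above the ceiling, or
    # part of an allowance run longer than permitted
    breaker = ~(zero | allow)
    for s, e in _runs(allow):
        if e - s > allowance_max_epochs:
            breaker[s:e] = True
    nonwear = np.zeros(c.shape, dtype=bool)
    for s, e in _runs(~breaker):
        if e - s < zero_run_min:
            continue
        # trim edge interruptions: a window begins and ends on a zero epoch
        inner = np.flatnonzero(zero[s:e])
        if inner.size == 0:
            continue
        s2, e2 = s + inner[0], s + inner[-1] + 1
        if e2 - s2 >= zero_run_min:
            nonwear[s2:e2] = True
    return nonwear


def detect_nonwear(
    day: EpochDay,
    zero_run_min: int = 60,
    allowance_max_epochs: int = 2,
    allowance_cpm_max: int = 100,
) -> WearMask:
    """Derive the wear mask of one day (wear = complement of nonwear)."""
    return WearMask(~nonwear_mask(day.counts, zero_run_min,
                                  allowance_max_epochs, allowance_cpm_max))


def classify_epochs(
    day: EpochDay,
    mask: WearMask,
    cuts: CutPoints = CutPoints(),
    min_wear_minutes: int = DEFAULT_MIN_WEAR_MINUTES,
) -> DailySummary:
    """Assign each worn epoch one intensity band and summarise the day.

    Nonwear epochs are counted nowhere (nonwear is not sedentary).  The day is
    valid when wear time reaches ``min_wear_minutes`` (default 10 h).
    """
    c = day.counts
    worn = mask.flags
    if worn.shape != c.shape:
        raise ValueError("wear mask length does not match the day")
    wear = int(worn.sum())
    sed = int((worn & (c <= cuts.sedentary_max)).sum())
    light = int((worn & (c > cuts.sedentary_max) & (c <= cuts.light_max)).sum())
    mod = int((worn & (c > cuts.light_max) & (c <= cuts.moderate_max)).sum())
    vig = int((worn & (c > cuts.moderate_max)).sum())
    return DailySummary(
        participant_id=day.participant_id,
        date=day.date,
        wear_min=wear,
        sedentary_min=sed,
        light_min=light,
        moderate_min=mod,
        vigorous_min=vig,
        valid=wear >= min_wear_minutes,
    )


def weekly_accel_estimate(
    days: Sequence[DailySummary],
    min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
    scale_days: int = 7,
) -> Optional[WeeklyEstimate]:
    """Weekly accelerometer summary from one participant's daily summaries.

    Participants with fewer than ``min_valid_days`` valid days get no estimate
    (None) and drop out of device comparisons under complete-case analysis.
    Otherwise each intensity's weekly value is the mean over valid days scaled
    to ``scale_days`` (minutes/week).
    """
    valid = [d for d in days if d.valid]
    if len(valid) < min_valid_days:
        return None
    sed = float(np.mean([d.sedentary_min for d in valid])) * scale_days
    mod = float(np.mean([d.moderate_min for d in valid])) * scale_days
    vig = float(np.mean([d.vigorous_min for d in valid])) * scale_days
    return WeeklyEstimate(
        instrument="accelerometer",
        sedentary_min_wk=sed,
        moderate_min_wk=mod,
        vigorous_min_wk=vig,
        mvpa_min_wk=mod + vig,
        n_days_used=len(valid),
    )


def summarize_days(
    days: Iterable[EpochDay],
    cuts: CutPoints = CutPoints(),
    min_wear_minutes: int = DEFAULT_MIN_WEAR_MINUTES,
) -> pd.DataFrame:
    """Nonwear-screen and classify a collection of days into a tidy frame."""
    rows = []
    for day in days:
        s = classify_epochs(day, detect_nonwear(day), cuts, min_wear_minutes)
        rows.append(
            (s.participant_id, s.date, s.wear_min, s.sedentary_min, s.light_min,
             s.moderate_min, s.vigorous_min, s.valid)
        )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "date", "wear_min", "sedentary_min",
                 "light_min", "moderate_min", "vigorous_min", "valid"],
    )


def weekly_from_daily(
    daily: pd.DataFrame,
    min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
    scale_days: int = 7,
) -> pd.DataFrame:
    """Per-participant weekly accelerometer estimates from a daily frame.

    Participants failing the valid-day rule are omitted from the result.
    """
    rows = []
    for pid, grp in daily.groupby("participant_id", sort=True):
        valid = grp[grp["valid"]]
        if len(valid) < min_valid_days:
            continue
        sed = valid["sedentary_min"].mean() * scale_days
        mod = valid["moderate_min"].mean() * scale_days
        vig = valid["vigorous_min"].mean() * scale_days
        rows.append((pid, sed, mod, vig, mod + vig, len(valid)))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "sedentary_min_wk", "moderate_min_wk",
                 "vigorous_min_wk", "mvpa_min_wk", "n_valid_days"],
    )


def read_epoch_csv(path: str | Path, participant_id: Optional[str] = None) -> list[EpochDay]:
    """Read minute-epoch days from CSV.

    Accepts the cohort dialect ``participant_id,date,minute,counts`` (minute
    0-1439) or a two-column per-participant ``timestamp,counts`` export
    resembling ActiGraph 60-s CSVs (``participant_id`` then names the wearer).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"participant_id", "date", "minute", "counts"} <= cols:
        pass
    elif {"timestamp", "counts"} <= cols:
        if participant_id is None:
            participant_id = Path(path).stem
        ts = pd.to_datetime(df["timestamp"])
        df = pd.DataFrame({
            "participant_id": participant_id,
            "date": ts.dt.date,
            "minute": ts.dt.hour * 60 + ts.dt.minute,
            "counts": df["counts"],
        })
    else:
        raise ValueError(
            f"{path}: expected columns participant_id,date,minute,counts "
            "or timestamp,counts"
        )
    days = []
    for (pid, date), grp in df.groupby(["participant_id", "date"], sort=True):
        if len(grp) != MINUTES_PER_DAY or set(grp["minute"]) != set(range(MINUTES_PER_DAY)):
            raise ValueError(
                f"{path}: participant {pid} date {date} does not cover minutes 0-1439"
            )
        counts = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
        counts[grp["minute"].to_numpy()] = grp["counts"].to_numpy()
        date = date if isinstance(date, _dt.date) else pd.Timestamp(date).date()
        days.append(EpochDay(str(pid), date, counts))
    return days
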