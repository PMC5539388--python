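"""Synthetic cohort generator with known ground truth.

The real study cohort (238 adults wearing a hip accelerometer for 7 days
while answering a once-daily activity diary plus BRFSS-, IPAQ- and
screen-time-style questionnaires) was never deposited, so this module
fabricates one with the same statistical structure and a fully known truth:

* minute-epoch count days with an overnight zero block, occasional daytime
  nonwear blocks, and planted contiguous moderate/vigorous bouts whose counts
  fall in the corresponding cut-point bands;
* right-skewed (gamma) daily activity-minute distributions, so cohort PA
  summaries are positively skewed and fail Shapiro-Wilk normality, as the
  study observed;
* EMA diary categories derived from daily truth plus Gaussian reporting noise
  before binning, present with a completion probability;
* BRFSS/IPAQ/screen-time responses derived from weekly truth with a
  per-participant multiplicative lognormal over-reporting bias on the PA
  items, rounded to each item's response granularity.

Every wear/nonwear boundary is guarded by a light-intensity epoch so the
planted wear time is unambiguous under the 60-min/allowance nonwear rule, and
the generator's truth table supports exact parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .accelerometry import MINUTES_PER_DAY, EpochDay
from .ema import bin_ema_minutes  # noqa: F401  (re-exported: binning is defined here conceptually)

import datetime as _dt

#: calendar anchor for synthetic days (a Monday in the study year)
BASE_DATE = _dt.date(2012, 1, 2)

# count bands used when planting epochs (cut-point bands; light avoids the
# 0-100 allowance range so nonwear windows cannot leak across a guard epoch)
SEDENTARY_COUNTS = (0, 99)
LIGHT_COUNTS = (101, 1951)
MODERATE_COUNTS = (1952, 5724)
VIGOROUS_COUNTS = (5725, 9000)


@dataclass(frozen=True)
class CohortParams:
    """Generating conditions for one synthetic cohort.

    Defaults emulate the study: 238 participants x 7 days, right-skewed
    activity (gamma with shape ``activity_dispersion``), ~93% diary completion,
    imperfect device compliance, and questionnaires that over-report true
    weekly PA by a multiplicative factor with a large coefficient of
    variation.
    """

    n_participants: int = 238
    n_days: int = 7
    seed: int = 0
    mean_daily_moderate_min: float = 22.0
    mean_daily_vigorous_min: float = 1.5
    activity_dispersion: float = 1.0
    wake_minutes_mean: float = 950.0
    wake_minutes_sd: float = 80.0
    nonwear_block_rate: float = 0.3
    nonwear_block_len_min: int = 60
    nonwear_block_len_max: int = 180
    ema_noise_sd: float = 10.0
    questionnaire_bias_factor: float = 3.8
    questionnaire_noise_cv: float = 0.9
    ema_completion_prob: float = 0.93
    accel_compliance_prob: float = 0.65

    def __post_init__(self) -> None:
        def bad(name, why):
            raise ValueError(f"invalid CohortParams.{name}: {why}")

        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                bad(f.name, f"must be finite, got {v!r}")
        if self.n_participants < 1:
            bad("n_participants", "must be >= 1")
        if self.n_days < 1:
            bad("n_days", "must be >= 1")
        for name in ("mean_daily_moderate_min", "mean_daily_vigorous_min",
                     "nonwear_block_rate", "ema_noise_sd",
                     "questionnaire_bias_factor", "questionnaire_noise_cv",
                     "wake_minutes_sd"):
            if getattr(self, name) < 0:
                bad(name, "must be >= 0")
        if self.activity_dispersion <= 0:
            bad("activity_dispersion", "must be > 0")
        if not (600 < self.wake_minutes_mean <= MINUTES_PER_DAY):
            bad("wake_minutes_mean", "must lie in (600, 1440]")
        if self.nonwear_block_len_min < 60:
            bad("nonwear_block_len_min", "detectable blocks need >= 60 min")
        if self.nonwear_block_len_max < self.nonwear_block_len_min:
            bad("nonwear_block_len_max", "must be >= nonwear_block_len_min")
        for name in ("ema_completion_prob", "accel_compliance_prob"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                bad(name, "must be a probability in [0, 1]")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth behind one synthetic cohort.

    ``daily`` has one row per participant-day with the planted intensity
    minutes (which partition true wear time); ``participant`` records the
    realized multiplicative bias of each questionnaire.  Non-compliant days
    keep their behavioral truth — only the device record is all zeros.
    """

    daily: pd.DataFrame
    participant: pd.DataFrame


@dataclass(frozen=True)
class InstrumentResponses:
    """Raw instrument answers before scoring (one frame per instrument)."""

    ema: pd.DataFrame          # participant_id, day, moderate_category, vigorous_category
    brfss: pd.DataFrame        # duration/frequency items, one row per participant
    ipaq: pd.DataFrame         # five activity items + sitting, one row per participant
    screen_time: pd.DataFrame  # tv/computer x weekday/weekend hours


def _split_integer(rng: np.random.Generator, total: int, parts: int, min_each: int) -> np.ndarray:
    """Random composition of ``total`` into ``parts`` integers each >= min_each."""
    spare = total - parts * min_each
    if spare < 0:
        raise ValueError("total too small to split")
    if spare == 0:
        return np.full(parts, min_each)
    cuts = np.sort(rng.integers(0, spare + 1, size=parts - 1))
    pieces = np.diff(np.concatenate(([0], cuts, [spare])))
    return pieces + min_each


def _lognormal_multiplier(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal multiplier(s) with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def _assemble_day(
    rng: np.random.Generator,
    wake: int,
    nonwear_lens: list[int],
    moderate: int,
    vigorous: int,
) -> tuple[np.ndarray, dict]:
    """Build one 1440-minute count vector and report the realized truth.

    Layout: [overnight zeros][wear region][overnight zeros], where the wear
    region interleaves light chunks with one sedentary block and contiguous
    moderate/vigorous bouts in random order.  Daytime nonwear blocks are
    inserted inside light chunks so every zero block is flanked by
    light-intensity guard epochs (>100 cpm), keeping truth unambiguous under
    the allowance rule.
    """
    sleep = MINUTES_PER_DAY - wake
    s1 = int(round(sleep * rng.uniform(0.3, 0.7)))
    s2 = sleep - s1

    k = len(nonwear_lens)
    wear = wake - sum(nonwear_lens)
    reserve = 4 + 2 * k  # four light chunks >=1 plus guards around inserts
    if wear < reserve + 2:
        nonwear_lens, k = [], 0
        wear = wake
    # cap planted activity so light guards always fit
    total_active = moderate + vigorous
    if total_active > wear - reserve:
        scale = (wear - reserve) / total_active if total_active else 0.0
        moderate = max(0, int(moderate * scale))
        vigorous = max(0, int(vigorous * scale))
    sed_frac = rng.uniform(0.45, 0.65)
    sedentary = int((wear - moderate - vigorous - reserve) * sed_frac)
    light = wear - moderate - vigorous - sedentary

    light_chunks = _split_integer(rng, light, 4, 1)
    activity = [("S", sedentary), ("M", moderate), ("V", vigorous)]
    order = rng.permutation(3)
    blocks = [("L", int(light_chunks[0]))]
    for i, j in enumerate(order):
        blocks.append(activity[j])
        blocks.append(("L", int(light_chunks[i + 1])))

    # drop daytime nonwear blocks into light chunks (>=1 light on each side)
    for nl in nonwear_lens:
        candidates = [i for i, (kind, ln) in enumerate(blocks) if kind == "L" and ln >= 2]
        i = candidates[rng.integers(len(candidates))]
        ln = blocks[i][1]
        left = int(rng.integers(1, ln))
        blocks[i] = ("L", left)
        blocks.insert(i + 1, ("L", ln - left))
        blocks.insert(i + 1, ("Z", nl))

    pieces = [np.zeros(s1, dtype=np.int64)]
    band = {"S": SEDENTARY_COUNTS, "L": LIGHT_COUNTS,
            "M": MODERATE_COUNTS, "V": VIGOROUS_COUNTS}
    for kind, ln in blocks:
        if ln == 0:
            continue
        if kind == "Z":
            pieces.append(np.zeros(ln, dtype=np.int64))
        else:
            lo, hi = band[kind]
            pieces.append(rng.integers(lo, hi + 1, size=ln, dtype=np.int64))
    pieces.append(np.zeros(s2, dtype=np.int64))
    counts = np.concatenate(pieces)
    assert counts.shape == (MINUTES_PER_DAY,)

    truth = {"moderate": moderate, "vigorous": vigorous,
             "sedentary": sedentary, "light": light, "wear": wear}
    return counts, truth


def _daily_activity(rng: np.random.Generator, mean: float, shape: float, n: int) -> np.ndarray:
    """Right-skewed integer daily minutes with the requested mean."""
    if mean == 0:
        return np.zeros(n, dtype=np.int64)
    draws = rng.gamma(shape, mean / shape, size=n)
    return np.rint(draws).astype(np.int64)


def generate_cohort(
    params: CohortParams,
) -> tuple[CohortTruth, list[EpochDay], InstrumentResponses]:
    """Generate a complete synthetic study with known ground truth.

    Returns the truth tables, the minute-epoch days (one per participant-day;
    non-compliant days are recorded as all zeros), and the raw responses of
    all four self-report instruments.  Identical params (including the seed)
    give byte-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n, d = params.n_participants, params.n_days
    width = len(str(n))
    pids = [f"P{str(i + 1).zfill(width)}" for i in range(n)]

    daily_rows = []
    epoch_days: list[EpochDay] = []
    ema_rows = []
    brfss_rows = []
    ipaq_rows = []
    screen_rows = []
    part_rows = []

    for pid in pids:
        mod = _daily_activity(rng, params.mean_daily_moderate_min,
                              params.activity_dispersion, d)
        vig = _daily_activity(rng, params.mean_daily_vigorous_min,
                              params.activity_dispersion, d)
        worn = rng.random(d) < params.accel_compliance_prob
        wake = np.clip(
            np.rint(rng.normal(params.wake_minutes_mean, params.wake_minutes_sd, size=d)),
            240, MINUTES_PER_DAY,
        ).astype(int)

        truths = []
        for j in range(d):
            k = rng.poisson(params.nonwear_block_rate)
            lens = [int(rng.integers(params.nonwear_block_len_min,
                                     params.nonwear_block_len_max + 1))
                    for _ in range(k)]
            counts, t = _assemble_day(rng, int(wake[j]), lens, int(mod[j]), int(vig[j]))
            truths.append(t)
            if not worn[j]:
                counts = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
            epoch_days.append(EpochDay(pid, BASE_DATE + _dt.timedelta(days=j), counts))
            daily_rows.append((pid, j + 1, t["moderate"], t["vigorous"],
                               t["light"], t["sedentary"], t["wear"], bool(worn[j])))

        # --- EMA daily diary: truth + Gaussian noise, truncated at 0, binned
        for j in range(d):
            if rng.random() >= params.ema_completion_prob:
                continue
            tm = max(0.0, truths[j]["moderate"] + rng.normal(0, params.ema_noise_sd))
            tv = max(0.0, truths[j]["vigorous"] + rng.normal(0, params.ema_noise_sd))
            ema_rows.append((pid, j + 1, bin_ema_minutes(tm), bin_ema_minutes(tv)))

        week_mod = float(sum(t["moderate"] for t in truths))
        week_vig = float(sum(t["vigorous"] for t in truths))
        active_mod = max(1, int(sum(t["moderate"] >= 1 for t in truths)))
        active_vig = max(1, int(sum(t["vigorous"] >= 1 for t in truths)))
        mean_sed = float(np.mean([t["sedentary"] for t in truths]))

        bias_brfss = params.questionnaire_bias_factor * _lognormal_multiplier(
            rng, params.questionnaire_noise_cv)
        bias_ipaq = params.questionnaire_bias_factor * _lognormal_multiplier(
            rng, params.questionnaire_noise_cv)
        part_rows.append((pid, float(bias_brfss), float(bias_ipaq)))

        # --- BRFSS: duration (min/day, whole minutes) x frequency (times/week)
        bm, bv = week_mod * bias_brfss, week_vig * bias_brfss
        mod_times = active_mod if bm >= 0.5 else 0
        vig_times = active_vig if bv >= 0.5 else 0
        brfss_rows.append((
            pid,
            round(bm / mod_times) if mod_times else 0, mod_times,
            round(bv / vig_times) if vig_times else 0, vig_times,
        ))

        # --- IPAQ: moderate split 60/40 between occupational moderate and
        # transport walking; vigorous all occupational; hours reported to the
        # minute.  Sitting items carry reporting noise but no PA bias.
        im, iv = week_mod * bias_ipaq, week_vig * bias_ipaq
        occ_mod_min, tw_min = 0.6 * im, 0.4 * im
        sit_noise = _lognormal_multiplier(rng, params.questionnaire_noise_cv)
        sit_min = min(MINUTES_PER_DAY, round(mean_sed * sit_noise))
        ipaq_rows.append((
            pid,
            active_vig if iv >= 0.5 else 0,
            round(iv / active_vig) / 60.0 if iv >= 0.5 else 0.0,
            active_mod if occ_mod_min >= 0.5 else 0,
            round(occ_mod_min / active_mod) / 60.0 if occ_mod_min >= 0.5 else 0.0,
            0, 0.0,  # occupational walking unused by this cohort
            active_mod if tw_min >= 0.5 else 0,
            round(tw_min / active_mod) / 60.0 if tw_min >= 0.5 else 0.0,
            0, 0.0,  # transport bicycling unused by this cohort
            sit_min / 60.0, sit_min / 60.0,
        ))

        # --- screen time: all sedentary truth attributed to TV (60%) and
        # computer (40%), same on weekdays and weekends, whole minutes
        st_noise = _lognormal_multiplier(rng, params.questionnaire_noise_cv)
        total = min(MINUTES_PER_DAY, round(mean_sed * st_noise))
        tv = round(0.6 * mean_sed * st_noise)
        tv = min(tv, total)
        comp = total - tv
        screen_rows.append((pid, tv / 60.0, tv / 60.0, comp / 60.0, comp / 60.0))

    truth = CohortTruth(
        daily=pd.DataFrame(
            daily_rows,
            columns=["participant_id", "day", "true_moderate_min",
                     "true_vigorous_min", "true_light_min",
                     "true_sedentary_min", "true_wear_min", "device_worn"],
        ),
        participant=pd.DataFrame(
            part_rows, columns=["participant_id", "brfss_bias", "ipaq_bias"]),
    )
    responses = InstrumentResponses(
        ema=pd.DataFrame(
            ema_rows,
            columns=["participant_id", "day", "moderate_category", "vigorous_category"]),
        brfss=pd.DataFrame(
            brfss_rows,
            columns=["participant_id", "moderate_min_per_day", "moderate_times_per_week",
                     "vigorous_min_per_day", "vigorous_times_per_week"]),
        ipaq=pd.DataFrame(
            ipaq_rows,
            columns=["participant_id",
                     "occ_vigorous_days", "occ_vigorous_hours",
                     "occ_moderate_days", "occ_moderate_hours",
                     "occ_walking_days", "occ_walking_hours",
                     "transport_walking_days", "transport_walking_hours",
                     "transport_bicycling_days", "transport_bicycling_hours",
                     "sitting_hours_weekday", "sitting_hours_weekend"]),
        screen_time=pd.DataFrame(
            screen_rows,
            columns=["participant_id", "tv_weekday_h", "tv_weekend_h",
                     "computer_weekday_h", "computer_weekend_h"]),
    )
    return truth, epoch_days, responses


def write_cohort_csvs(
    truth: CohortTruth,
    epoch_days: list[EpochDay],
    responses: InstrumentResponses,
    outdir: str | Path,
    write_epochs: bool = True,
) -> dict[str, Path]:
    """Write the cohort to the CSV dialects documented in docs/data_dictionary.md."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if write_epochs:
        frames = []
        minute = np.arange(MINUTES_PER_DAY)
        for day in epoch_days:
            frames.append(pd.DataFrame({
                "participant_id": day.participant_id,
                "date": day.date.isoformat(),
                "minute": minute,
                "counts": day.counts,
            }))
        paths["epochs"] = out / "epochs.csv"
        pd.concat(frames, ignore_index=True).to_csv(paths["epochs"], index=False)
    for name, df in [("ema", responses.ema), ("brfss", responses.brfss),
                     ("ipaq", responses.ipaq), ("screen_time", responses.screen_time),
                     ("truth_daily", truth.daily), ("truth_participant", truth.participant)]:
        paths[name] = out / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    return paths
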