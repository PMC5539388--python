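"""Study orchestration: generate -> process -> score -> compare.

Runs the whole convergent-validity analysis as a configured, seeded,
reproducible unit and emits the report tables:

* descriptives per instrument x intensity (mean, SD, quartiles, Shapiro-Wilk
  normality p);
* Spearman correlation matrix cells with Holm-adjusted significance;
* Lin concordance agreement cells (LCC, 95% CI, Pearson r and p, BCF) of each
  self-report instrument against the accelerometer;
* Bland-Altman summaries and plot coordinates on log-transformed MVPA, plus
  concordance plot coordinates;
* a run manifest (config echo, seed, version, per-stage record counts).

All comparisons are complete-case: each cell uses exactly the participants
with both estimates present, so cell sample sizes differ.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .accelerometry import (
    CutPoints,
    DEFAULT_MIN_VALID_DAYS,
    DEFAULT_MIN_WEAR_MINUTES,
    summarize_days,
    weekly_from_daily,
)
from .agreement import (
    AgreementResult,
    PairedSample,
    bland_altman_log,
    holm_adjust,
    lin_ccc,
    spearman,
)
from .ema import ema_midpoints
from .instruments import score_cohort
from .synthetic import CohortParams, generate_cohort, write_cohort_csvs

#: instruments carrying each intensity, in report order
INSTRUMENTS_BY_INTENSITY = {
    "sedentary": ("screen_time", "ipaq", "accelerometer"),
    "moderate": ("ema", "brfss", "ipaq", "accelerometer"),
    "vigorous": ("ema", "brfss", "ipaq", "accelerometer"),
    "mvpa": ("ema", "brfss", "ipaq", "accelerometer"),
}
SELF_REPORTS = ("ema", "brfss", "ipaq", "screen_time")


class ConfigError(ValueError):
    """Invalid or inconsistent study configuration."""


class DataError(ValueError):
    """Malformed input data (schema or value violations)."""


@dataclass(frozen=True)
class StudyConfig:
    """Everything a run needs; identical config + seed implies identical output."""

    cohort: CohortParams = CohortParams()
    cuts: CutPoints = CutPoints()
    min_wear_minutes: int = DEFAULT_MIN_WEAR_MINUTES
    min_valid_days: int = DEFAULT_MIN_VALID_DAYS
    ema_top_category_minutes: float = 70.0
    rescale_ema_to_7_days: bool = False
    log_offset: float = 1.0
    ci_level: float = 0.95
    alpha: float = 0.05
    holm_family: str = "intensity"  # or "table"
    lcc_log_transform: bool = False
    write_epochs: bool = False

    def __post_init__(self) -> None:
        if self.min_wear_minutes <= 0 or self.min_valid_days <= 0:
            raise ConfigError("validity thresholds must be positive")
        if not (0 < self.ci_level < 1) or not (0 < self.alpha < 1):
            raise ConfigError("ci_level and alpha must lie in (0, 1)")
        if self.holm_family not in ("intensity", "table"):
            raise ConfigError("holm_family must be 'intensity' or 'table'")

    @property
    def midpoints(self) -> tuple[float, ...]:
        return ema_midpoints(self.ema_top_category_minutes)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: Optional[int] = None) -> "StudyConfig":
        import yaml

        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            cohort = CohortParams(**raw.pop("cohort", {}))
            cuts = CutPoints(**raw.pop("cuts", {}))
            if seed is not None:
                cohort = dataclasses.replace(cohort, seed=seed)
            return cls(cohort=cohort, cuts=cuts, **raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass(frozen=True)
class DescriptiveRow:
    label: str
    n: int
    mean: float
    sd: float
    p25: float
    p50: float
    p75: float
    shapiro_p: Optional[float]


@dataclass
class StudyResult:
    """In-memory report bundle of one run."""

    estimates: pd.DataFrame
    daily: pd.DataFrame
    weekly_accel: pd.DataFrame
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    agreement: pd.DataFrame
    bland_altman: pd.DataFrame
    bland_altman_points: pd.DataFrame
    concordance_points: pd.DataFrame
    overreporting: pd.DataFrame
    manifest: dict


def descriptives(values, label: str = "") -> DescriptiveRow:
    """Mean, sample SD, quartiles (linear interpolation) and Shapiro-Wilk p.

    Shapiro-Wilk needs n >= 3 and non-constant data; otherwise the p-value is
    omitted (None).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise DataError(f"descriptives({label!r}): empty vector")
    p25, p50, p75 = np.percentile(v, [25, 50, 75])
    shapiro_p: Optional[float] = None
    if v.size >= 3 and np.ptp(v) > 0:
        shapiro_p = float(stats.shapiro(v).pvalue)
    return DescriptiveRow(
        label=label,
        n=int(v.size),
        mean=float(np.mean(v)),
        sd=float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        p25=float(p25), p50=float(p50), p75=float(p75),
        shapiro_p=shapiro_p,
    )


def _pivot(estimates: pd.DataFrame) -> pd.DataFrame:
    """Wide participant x (instrument, intensity) table of minutes/week."""
    return estimates.pivot_table(
        index="participant_id", columns=["instrument", "intensity"],
        values="minutes_per_week", aggfunc="first")


def complete_case_pairs(
    estimates: pd.DataFrame,
    instrument_a: str,
    instrument_b: str,
    intensity: str,
) -> Optional[PairedSample]:
    """Paired vectors restricted to participants with both values present."""
    wide = _pivot(estimates)
    try:
        a = wide[(instrument_a, intensity)]
        b = wide[(instrument_b, intensity)]
    except KeyError:
        return None
    keep = a.notna() & b.notna()
    if keep.sum() == 0:
        return None
    return PairedSample(a[keep].to_numpy(float), b[keep].to_numpy(float))


def descriptives_table(estimates: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for intensity, instruments in INSTRUMENTS_BY_INTENSITY.items():
        for inst in instruments:
            v = estimates.query(
                "instrument == @inst and intensity == @intensity")["minutes_per_week"]
            if v.empty:
                continue
            d = descriptives(v, f"{inst}:{intensity}")
            rows.append((intensity, inst, d.n, d.mean, d.sd, d.p25, d.p50, d.p75,
                         d.shapiro_p))
    return pd.DataFrame(
        rows, columns=["intensity", "instrument", "n", "mean", "sd",
                       "p25", "p50", "p75", "shapiro_p"])


def correlation_table(
    estimates: pd.DataFrame,
    alpha: float = 0.05,
    holm_family: str = "intensity",
) -> pd.DataFrame:
    """Spearman rho, p and n for every instrument pair within each intensity.

    Holm's step-down adjustment is applied per intensity row by default
    (``holm_family='intensity'``) or over the whole table (``'table'``).
    """
    rows = []
    for intensity, instruments in INSTRUMENTS_BY_INTENSITY.items():
        for i, a in enumerate(instruments):
            for b in instruments[i + 1:]:
                sample = complete_case_pairs(estimates, a, b, intensity)
                if sample is None or sample.n < 3:
                    rows.append((intensity, a, b, 0 if sample is None else sample.n,
                                 math.nan, math.nan))
                    continue
                rho, p = spearman(sample)
                rows.append((intensity, a, b, sample.n, rho, p))
    df = pd.DataFrame(
        rows, columns=["intensity", "instrument_a", "instrument_b", "n", "rho", "p"])
    df["holm_significant"] = False
    if holm_family == "table":
        df["holm_significant"] = holm_adjust(df["p"].to_numpy(), alpha)
    else:
        for intensity in df["intensity"].unique():
            m = df["intensity"] == intensity
            df.loc[m, "holm_significant"] = holm_adjust(df.loc[m, "p"].to_numpy(), alpha)
    return df


def agreement_table(
    estimates: pd.DataFrame,
    ci_level: float = 0.95,
    alpha: float = 0.05,
    holm_family: str = "intensity",
    lcc_log_transform: bool = False,
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Each self-report instrument vs the accelerometer, per intensity.

    Emits every cell (NA-marked when missing) so downstream diffing is stable.
    """
    corr = correlation_table(estimates, alpha, holm_family)
    rows = []
    for intensity, instruments in INSTRUMENTS_BY_INTENSITY.items():
        for inst in instruments:
            if inst == "accelerometer":
                continue
            sample = complete_case_pairs(estimates, inst, "accelerometer", intensity)
            cell = corr[(corr["intensity"] == intensity)
                        & (corr["instrument_a"] == inst)
                        & (corr["instrument_b"] == "accelerometer")]
            holm = bool(cell["holm_significant"].iloc[0]) if len(cell) else None
            rho = float(cell["rho"].iloc[0]) if len(cell) else math.nan
            rho_p = float(cell["p"].iloc[0]) if len(cell) else math.nan
            if sample is None or sample.n < 3:
                rows.append((intensity, inst, 0 if sample is None else sample.n,
                             rho, rho_p, holm, *(math.nan,) * 6))
                continue
            cc = lin_ccc(sample, ci_level, lcc_log_transform, log_offset)
            if cc is None:
                rows.append((intensity, inst, sample.n, rho, rho_p, holm,
                             *(math.nan,) * 6))
                continue
            rows.append((intensity, inst, sample.n, rho, rho_p, holm,
                         cc.lcc, cc.lcc_ci_low, cc.lcc_ci_high,
                         cc.pearson_r, cc.pearson_p, cc.bcf))
    return pd.DataFrame(
        rows, columns=["intensity", "instrument", "n", "spearman_rho", "spearman_p",
                       "holm_significant", "lcc", "lcc_ci_low", "lcc_ci_high",
                       "pearson_r", "pearson_p", "bcf"])


def bland_altman_tables(
    estimates: pd.DataFrame,
    intensity: str = "mvpa",
    offset: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-instrument Bland-Altman summaries and plot coordinates vs device."""
    summaries, points = [], []
    for inst in INSTRUMENTS_BY_INTENSITY[intensity]:
        if inst == "accelerometer":
            continue
        sample = complete_case_pairs(estimates, inst, "accelerometer", intensity)
        if sample is None or sample.n < 3:
            summaries.append((intensity, inst, 0 if sample is None else sample.n,
                              math.nan, math.nan, math.nan))
            continue
        ba = bland_altman_log(sample, offset)
        summaries.append((intensity, inst, ba.n, ba.mean_diff, ba.loa_low, ba.loa_high))
        points.append(pd.DataFrame({
            "intensity": intensity, "instrument": inst,
            "mean_log": ba.means, "diff_log": ba.diffs,
        }))
    summary_df = pd.DataFrame(
        summaries, columns=["intensity", "instrument", "n",
                            "mean_diff_log", "loa_low_log", "loa_high_log"])
    points_df = (pd.concat(points, ignore_index=True) if points
                 else pd.DataFrame(columns=["intensity", "instrument",
                                            "mean_log", "diff_log"]))
    return summary_df, points_df


def concordance_points(estimates: pd.DataFrame) -> pd.DataFrame:
    """Raw (instrument, accelerometer) pairs for concordance plots."""
    wide = _pivot(estimates)
    frames = []
    for intensity, instruments in INSTRUMENTS_BY_INTENSITY.items():
        if ("accelerometer", intensity) not in wide.columns:
            continue
        for inst in instruments:
            if inst == "accelerometer" or (inst, intensity) not in wide.columns:
                continue
            a, b = wide[(inst, intensity)], wide[("accelerometer", intensity)]
            keep = a.notna() & b.notna()
            frames.append(pd.DataFrame({
                "intensity": intensity, "instrument": inst,
                "participant_id": wide.index[keep],
                "instrument_min_wk": a[keep].to_numpy(float),
                "accelerometer_min_wk": b[keep].to_numpy(float),
            }))
    if not frames:
        return pd.DataFrame(columns=["intensity", "instrument", "participant_id",
                                     "instrument_min_wk", "accelerometer_min_wk"])
    return pd.concat(frames, ignore_index=True)


def overreporting_summary(
    estimates: pd.DataFrame, intensity: str = "mvpa"
) -> pd.DataFrame:
    """Difference of cohort means (instrument - accelerometer), min/week.

    Computed on each instrument's complete cases against the device, the
    summary behind statements like "over-reporting of an average of X min per
    week of MVPA".
    """
    rows = []
    for inst in INSTRUMENTS_BY_INTENSITY[intensity]:
        if inst == "accelerometer":
            continue
        sample = complete_case_pairs(estimates, inst, "accelerometer", intensity)
        if sample is None:
            rows.append((intensity, inst, 0, math.nan, math.nan, math.nan))
            continue
        im, am = float(np.mean(sample.x)), float(np.mean(sample.y))
        rows.append((intensity, inst, sample.n, im, am, im - am))
    return pd.DataFrame(
        rows, columns=["intensity", "instrument", "n", "instrument_mean",
                       "accelerometer_mean", "mean_difference"])


def eligibility_percent(enrolled: int, screened: int) -> int:
    """Enrolled share of screened candidates, as a whole percentage."""
    if screened <= 0 or enrolled < 0 or enrolled > screened:
        raise DataError("need 0 <= enrolled <= screened with screened > 0")
    return round(100 * enrolled / screened)


def possible_diary_assessments(n_participants: int, n_days: int) -> int:
    """Diary slots the protocol offers: one per participant per day."""
    return n_participants * n_days


def run_synthetic_study(config: StudyConfig) -> StudyResult:
    """Run the full pipeline on a generated cohort, entirely in memory."""
    truth, epoch_days, responses = generate_cohort(config.cohort)
    daily = summarize_days(epoch_days, config.cuts, config.min_wear_minutes)
    weekly = weekly_from_daily(daily, config.min_valid_days)

    est_self = score_cohort(responses.ema, responses.brfss, responses.ipaq,
                            responses.screen_time, config.midpoints,
                            config.rescale_ema_to_7_days)
    est_accel = weekly.melt(
        id_vars="participant_id",
        value_vars=["sedentary_min_wk", "moderate_min_wk", "vigorous_min_wk",
                    "mvpa_min_wk"],
        var_name="intensity", value_name="minutes_per_week")
    est_accel["intensity"] = est_accel["intensity"].str.replace("_min_wk", "", regex=False)
    est_accel["instrument"] = "accelerometer"
    frames = [df for df in (est_self, est_accel[est_self.columns]) if not df.empty]
    estimates = pd.concat(frames, ignore_index=True).sort_values(
        ["instrument", "intensity", "participant_id"], ignore_index=True)

    result = compare_estimates(estimates, config)
    result.daily = daily
    result.weekly_accel = weekly

    n, d = config.cohort.n_participants, config.cohort.n_days
    n_valid = len(weekly)
    result.manifest = {
        "software": {"package": "paconcord", "version": __version__},
        "seed": config.cohort.seed,
        "config": config.to_dict(),
        "participants": {
            "enrolled": n,
            "with_valid_accelerometer": n_valid,
            "excluded_from_device_comparisons": n - n_valid,
        },
        "ema": {
            "possible_assessments": possible_diary_assessments(n, d),
            "completed_assessments": int(len(responses.ema)),
            "completion_pct": round(
                100.0 * len(responses.ema) / possible_diary_assessments(n, d), 1),
        },
        "records": {
            "epoch_days": len(epoch_days),
            "daily_summaries": int(len(daily)),
            "weekly_accelerometer_estimates": n_valid,
            "estimate_rows": int(len(estimates)),
        },
    }
    result._generated = (truth, epoch_days, responses)  # type: ignore[attr-defined]
    return result


def compare_estimates(estimates: pd.DataFrame, config: StudyConfig = StudyConfig()) -> StudyResult:
    """Descriptives + correlation + agreement battery on a tidy estimates table."""
    required = {"participant_id", "instrument", "intensity", "minutes_per_week"}
    if not required <= set(estimates.columns):
        raise DataError(
            f"estimates table must have columns {sorted(required)}, "
            f"got {sorted(estimates.columns)}")
    ba_summary, ba_points = bland_altman_tables(estimates, "mvpa", config.log_offset)
    return StudyResult(
        estimates=estimates,
        daily=pd.DataFrame(),
        weekly_accel=pd.DataFrame(),
        descriptives=descriptives_table(estimates),
        correlations=correlation_table(estimates, config.alpha, config.holm_family),
        agreement=agreement_table(estimates, config.ci_level, config.alpha,
                                  config.holm_family, config.lcc_log_transform,
                                  config.log_offset),
        bland_altman=ba_summary,
        bland_altman_points=ba_points,
        concordance_points=concordance_points(estimates),
        overreporting=overreporting_summary(estimates),
        manifest={"software": {"package": "paconcord", "version": __version__},
                  "config": config.to_dict(),
                  "records": {"estimate_rows": int(len(estimates))}},
    )


def write_report(result: StudyResult, outdir: str | Path) -> dict[str, Path]:
    """Write the report bundle as CSVs + manifest.json (NA cells explicit)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "estimates": result.estimates,
        "daily_summaries": result.daily,
        "weekly_accelerometer": result.weekly_accel,
        "descriptives": result.descriptives,
        "correlations": result.correlations,
        "agreement": result.agreement,
        "bland_altman": result.bland_altman,
        "bland_altman_points": result.bland_altman_points,
        "concordance_points": result.concordance_points,
        "overreporting": result.overreporting,
    }
    for name, df in tables.items():
        if df is None or df.empty and name in ("daily_summaries", "weekly_accelerometer"):
            continue
        paths[name] = out / f"{name}.csv"
        df.to_csv(paths[name], index=False, na_rep="NA")
    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return paths


def run_study(config: StudyConfig, outdir: str | Path) -> StudyResult:
    """Generate, process, score, compare and write the full report bundle."""
    result = run_synthetic_study(config)
    paths = write_report(result, outdir)
    if config.write_epochs:
        truth, epoch_days, responses = result._generated  # type: ignore[attr-defined]
        write_cohort_csvs(truth, epoch_days, responses, Path(outdir) / "cohort",
                          write_epochs=True)
    return result
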