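# Data dictionary

All files are plain CSV with a header row. Missing cells are written as `NA`.

## Cohort inputs (written by `pa-concord simulate`, read by `process`)

### `epochs.csv` — minute-epoch activity counts
| column | type | meaning |
|---|---|---|
| `participant_id` | string | opaque participant identifier |
| `date` | ISO date | calendar day of the recording |
| `minute` | int 0–1439 | minute of day of the 60-s epoch |
| `counts` | int ≥ 0 | activity counts in the epoch (cpm) |

Each (participant, date) must cover minutes 0–1439 exactly once. A
two-column `timestamp,counts` per-participant export (60-s epochs) is also
accepted by the reader.

### `ema.csv` — daily-diary responses
| column | type | meaning |
|---|---|---|
| `participant_id` | string | |
| `day` | int 1–7 | study day of the diary |
| `moderate_category` | int 1–8 or empty | response option for moderate-intensity minutes (0–9, 10–19, …, 60–69, ≥70) |
| `vigorous_category` | int 1–8 or empty | same, vigorous intensity |

Days with no completed diary are simply absent.

### `brfss.csv` — leisure-time duration × frequency items
| column | type | meaning |
|---|---|---|
| `participant_id` | string | |
| `moderate_min_per_day` | minutes | usual duration of moderate activity |
| `moderate_times_per_week` | count | usual weekly frequency (may exceed 7) |
| `vigorous_min_per_day` | minutes | |
| `vigorous_times_per_week` | count | |

### `ipaq.csv` — occupational/transport items plus sitting
Five activity items, each a `*_days` (0–7) / `*_hours` (hours/day) pair:
`occ_vigorous`, `occ_moderate`, `occ_walking`, `transport_walking`,
`transport_bicycling`; plus `sitting_hours_weekday` and
`sitting_hours_weekend` (hours/day, 0–24).

### `screen_time.csv` — sedentary screen hours
`participant_id`, `tv_weekday_h`, `tv_weekend_h`, `computer_weekday_h`,
`computer_weekend_h` — hours/day in [0, 24] by device and day type.

### `truth_daily.csv`, `truth_participant.csv` — synthetic ground truth
Per participant-day: `true_moderate_min`, `true_vigorous_min`,
`true_light_min`, `true_sedentary_min` (they sum to `true_wear_min`) and
`device_worn`. Per participant: the realized multiplicative reporting bias
of each questionnaire (`brfss_bias`, `ipaq_bias`). Used only by test
harnesses; a real study has no such file.

## Report outputs (written by `process`, `compare` and `all`)

### `estimates.csv` — the tidy common currency
One row per `participant_id × instrument × intensity` with
`minutes_per_week`. Instruments: `accelerometer`, `ema`, `brfss`, `ipaq`,
`screen_time`; intensities: `sedentary`, `moderate`, `vigorous`, `mvpa`.

### `daily_summaries.csv`
`participant_id`, `date`, `wear_min`, `sedentary_min`, `light_min`,
`moderate_min`, `vigorous_min`, `valid` (wear ≥ 10 h).

### `weekly_accelerometer.csv`
Per participant with ≥ 4 valid days: `sedentary_min_wk`, `moderate_min_wk`,
`vigorous_min_wk`, `mvpa_min_wk` (mean valid day × 7) and `n_valid_days`.

### `descriptives.csv`
Per instrument × intensity: `n`, `mean`, `sd`, `p25`, `p50`, `p75`,
`shapiro_p` (Shapiro–Wilk normality p; `NA` when undefined).

### `correlations.csv`
Per intensity and instrument pair: `n` (complete cases), Spearman `rho`,
`p`, and `holm_significant` after the step-down adjustment within the
configured family.

### `agreement.csv`
Per intensity, each self-report instrument vs the accelerometer: `n`,
`spearman_rho`, `spearman_p`, `holm_significant`, `lcc`, `lcc_ci_low`,
`lcc_ci_high`, `pearson_r`, `pearson_p`, `bcf`.

### `bland_altman.csv` / `bland_altman_points.csv`
MVPA limits of agreement on the log(x + offset) scale (`mean_diff_log`,
`loa_low_log`, `loa_high_log`) and the per-pair plot coordinates
(`mean_log`, `diff_log`).

### `concordance_points.csv`
Raw (instrument, accelerometer) minute/week pairs per intensity for
concordance plots.

### `overreporting.csv`
Per instrument: complete-case cohort means of instrument and device MVPA
and their difference (`mean_difference`, min/week).

### `manifest.json`
Config echo, seed, package version, and per-stage record counts
(participants enrolled / with valid device weeks / excluded, diary slots
possible / completed, rows per table).
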