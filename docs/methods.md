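# Methods

`paconcord` implements a convergent-validity analysis for physical-activity
(PA) measurement: how well do self-report instruments — a once-daily
ecological momentary assessment (EMA) diary, retrospective BRFSS- and
IPAQ-style questionnaires, and a screen-time scale — agree with hip-worn
accelerometry over the same 7-day window? Because the motivating study's
raw cohort was never deposited, the package pairs the analysis pipeline
with a synthetic-cohort generator whose ground truth is known exactly, so
every stage can be validated by parameter recovery rather than by
comparison to an unavailable dataset.

## Device processing

Accelerometer data enter as minute epochs (1440 counts/day). Processing
follows the standard screening chain for count-based actigraphy:

1. **Nonwear detection.** A nonwear period is ≥ 60 consecutive minutes of
   zero counts, allowing interruptions of at most 2 consecutive epochs with
   counts in (0, 100]; an epoch above 100 cpm, or a third consecutive
   nonzero epoch, terminates the period. Interruptions interior to a
   qualifying window count as nonwear; trailing interruptions belong to
   wear. Implementation is a vectorized run-length segmentation; the test
   suite checks it minute-for-minute against an independent regex
   enumeration of qualifying windows on random days. Windows are evaluated
   within a single calendar day; cross-midnight stitching is not applied
   (each day record stands alone).
2. **Cut-point classification.** Worn epochs map to intensity by counts:
   sedentary ≤ 99, light 100–1951, moderate 1952–5724, vigorous ≥ 5725 cpm
   (the standard adult Freedson thresholds; configurable via `CutPoints`).
   Nonwear minutes count toward no category — nonwear is not sedentary.
3. **Valid-day and weekly rules.** A day is valid with ≥ 10 h wear;
   participants with ≥ 4 valid days (of 7) get a weekly estimate, the mean
   over valid days × 7. The ×7 scaling is this package's choice to put
   device output in minutes/week, commensurate with the questionnaires; a
   plain "averaging daily estimates" leaves the unit ambiguous, and the
   scale factor is exposed (`scale_days`) for anyone preferring a different
   convention. Participants failing the rule are excluded from device
   comparisons (complete-case analysis).

## Instrument scoring

* **EMA**: each day's moderate and vigorous response category (8 options:
  0–9, 10–19, …, 60–69, ≥ 70 min) scores the mean of its span — 24.5 min
  for 20–29 — and the open-ended top category scores its lower bound, 70
  min (configurable; any larger imputation is speculative). Days are
  summed without rescaling for missed diaries, since a missed day is a
  missing observation, not a zero; an optional `rescale_to_7_days` switch
  exists but defaults off. Note the instrument's floor: a participant
  reporting zero activity still scores 4.5 min/day (category 1's
  midpoint), so weekly EMA estimates are bounded below by 4.5 × answered
  days — visible in cohort percentiles as multiples of 4.5.
* **BRFSS**: minutes/week = duration (min/day) × frequency (times/week)
  per intensity; missing components propagate to the affected intensity
  and to MVPA.
* **IPAQ**: per item, minutes/week = days × hours × 60; occupational
  vigorous counts as vigorous, while occupational moderate, both walking
  items and transport bicycling count as moderate. Sitting uses a
  (5 × weekday + 2 × weekend)/7 daily average × 60 × 7. The "at least 10
  minutes at a time" clause is treated as question wording, not a post-hoc
  filter, and no truncation caps (e.g. 960 min/day) are applied.
* **Screen time**: sedentary minutes/week = (weekday hours × 5 + weekend
  hours × 2) × 60 over TV + computer; combined totals above 24 h/day are
  impossible responses and rejected (or capped at 10 080 min/week on
  request).

## Agreement battery

All comparisons run on complete cases per cell, so cell sample sizes
differ. For paired weekly estimates (x = instrument, y = device):

* **Spearman ρ** with midranks for ties; two-sided p from
  t = ρ√((n−2)/(1−ρ²)) on n−2 df (accurate at the cohort sizes involved,
  n ≈ 170–240). Significance across a family of tests uses Holm's
  sequential step-down Bonferroni rule; the family defaults to all
  instrument pairs within one intensity (the most defensible reading of a
  per-row adjustment) and can be widened to the whole table.
* **Lin's concordance correlation coefficient (CCC)**
  ρ̂c = 2s_xy / (s_x² + s_y² + (x̄−ȳ)²), with biased (1/n) moment
  estimators — the original convention, which matters at small n. It
  factors as ρ̂c = r·C_b with C_b = 2/(v + 1/v + u²), v = s_x/s_y,
  u = (x̄−ȳ)/√(s_x s_y); the two forms are cross-checked to 1e-10 in
  tests. The 95% CI is built on the atanh (Fisher z) scale with Lin's
  asymptotic variance of the transformed estimate and back-transformed.
  The phrase "z-transformed estimates assessed using LCC" is implemented
  as a CI on the coefficient's atanh scale — atanh of raw minutes is
  undefined above 1 — with a `log_transform` switch for computing the
  coefficient on log(value + offset) data instead. Monte-Carlo checks
  confirm 93–97% coverage at n = 150.
* **Bland–Altman** on log(value + offset) transformed pairs: mean
  difference and mean ± 1.96 × sample SD limits, plus per-pair (mean,
  difference) coordinates for plotting. The default offset of +1 minute
  keeps legitimate zeros finite (device vigorous medians are 0); it is
  configurable, and a zero offset is accepted when the data allow it.

Descriptives report mean, sample SD (n−1), and 25th/50th/75th percentiles
by linear interpolation, with Shapiro–Wilk normality p-values from the
standard library routine.

## Synthetic cohort

Defaults emulate the motivating study's conditions: 238 participants × 7
days; diary completion probability 0.93; daily device-wear probability
0.65, which makes P(≥ 4 valid days of 7) ≈ 0.80, the share of participants
with valid device weeks the study reported; mean daily moderate/vigorous
minutes 22 and 1.5 (device-frame means of ~156 and ~7 min/week); gamma
daily-activity draws with shape 1 for the strong right skew that makes
cohort PA summaries fail Shapiro–Wilk; and a questionnaire over-reporting
bias factor of 3.8 with lognormal noise CV 0.9, sized to reproduce the
several-hundred-minute mean over-reporting and very large questionnaire
SDs seen in such validation cohorts.

Each day is assembled from segments: overnight zeros split around the wear
region, light-intensity chunks interleaved with one sedentary block and
contiguous moderate/vigorous bouts in random order, and Poisson-count
daytime nonwear blocks (≥ 60 min) inserted inside light chunks. Counts are
drawn uniformly within the target cut-point band (sedentary U[0,99],
light U[101,1951], moderate U[1952,5724], vigorous U[5725,9000]) — only
band membership matters downstream. Two deliberate guards keep the truth
exact: every wear/nonwear boundary carries a light epoch (> 100 cpm), so
zero blocks are delimited unambiguously under the allowance rule, and
light counts start at 101 so a boundary epoch can never be absorbed as an
allowance interruption. Consequently planted moderate/vigorous minutes are
recovered *exactly* by the device pipeline, a property the tests assert.

Self-reports derive from the truth: EMA categories are binned truth plus
Gaussian noise (SD 10 min/day, truncated at 0); BRFSS/IPAQ weekly values
are truth × a per-participant lognormal bias realization, decomposed into
the instrument's duration/frequency items with durations rounded to whole
minutes (so the noise-free round trip is exact to ≤ 3.5 min per item);
sedentary self-reports (IPAQ sitting, screen time) carry reporting noise
but not the PA over-reporting factor. Device non-compliance zeroes the
recording while leaving behavioral truth intact.

What the generator does **not** emulate: raw 30 Hz waveforms, triaxial
vector magnitudes, within-day autocorrelation beyond contiguous bouts,
weekday/weekend structure, demographic covariates of reporting bias, and
EMA sedentary items (the diary here covers moderate/vigorous only, so
sedentary comparisons involve the screen-time scale, IPAQ sitting and the
device). Passing recovery tests therefore demonstrate that the pipeline's
arithmetic is faithful, not that real humans report with these error
structures.

## Numerical and degenerate-input choices

Constant vectors leave Spearman and the CCC undefined: the functions warn
and return NaN/None rather than raise, and report tables carry explicit
`NA` cells so output shapes are stable. BCF is undefined at r = 0. The CI
collapses to a point at |ρ̂c| = 1. Holm treats NaN p-values as
non-rejections outside the family. All randomness flows from one
`numpy.random.Generator` seeded from the study config, making report
bundles byte-identical across reruns of the same config.

Problem sizes in the shipped test suite are chosen for fast, stable
checks: unit tests use cohorts of 12–60 participants; the Monte-Carlo
suites use 1000 random days (nonwear oracle), 1000 random samples (CCC
identities), 1000 simulated cohorts of n = 150 (CI coverage), and 100
full-size (238 × 7) seeded replicates for the instrument-ordering check.

## Known limitations

* The weekly ×7 scaling and the EMA top-category value are conventions,
  flagged and configurable, not facts about the instruments.
* The Holm family definition for a correlation table is ambiguous in
  general; per-intensity is the default and the composition is
  config-driven.
* Spearman p-values use the t-approximation; exact permutation is only
  sensible at n ≤ 10 and appears only in tests.
* The generator's bias model is multiplicative and participant-level; real
  over-reporting plausibly varies by item, day and social context.
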