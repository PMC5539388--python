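# paconcord

Convergent validity of self-reported physical activity against
accelerometry, as a reusable, tested pipeline.

Validation studies of physical-activity (PA) self-report ask a simple
question with fussy mechanics: when the same people wear a hip
accelerometer for a week *and* answer a once-daily mobile diary (ecological
momentary assessment, EMA) plus retrospective questionnaires (BRFSS-style
leisure items, IPAQ-style occupational/transport items, a screen-time
scale), how well do the instruments agree on minutes/week of sedentary,
moderate, vigorous and moderate-to-vigorous (MVPA) activity? `paconcord`
implements the full chain for epidemiologists and measurement researchers:

* **accelerometry** — Troiano-style nonwear screening (≥ 60 min of zero
  counts with a 1–2 min allowance ≤ 100 cpm), Freedson cut-point
  classification, the ≥ 10 h valid-day and ≥ 4 valid-day rules, and weekly
  summaries;
* **instruments** — faithful scoring of all four self-reports into the
  common minutes/week currency (EMA bin midpoints, BRFSS duration ×
  frequency, IPAQ days × hours × 60 with walking/bicycling as moderate,
  5/2-weighted screen hours);
* **agreement** — Spearman ρ with Holm's sequential Bonferroni adjustment,
  Lin's concordance correlation coefficient (CCC)

  ρ̂c = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²) = r · C_b,

  with its precision (Pearson r) / accuracy (bias correction factor C_b)
  decomposition and an atanh-scale 95% CI, and Bland–Altman limits of
  agreement on log-transformed MVPA;
* **synthetic_cohort** — a generator producing minute-epoch counts,
  nonwear, and all four instruments' responses from a known ground truth
  with controllable reporting bias and noise, enabling exact
  parameter-recovery tests where no real cohort is available.

## Worked example

```python
from paconcord import StudyConfig, CohortParams, run_synthetic_study

cfg = StudyConfig(cohort=CohortParams(seed=7))   # 238 participants x 7 days
res = run_synthetic_study(cfg)

m = res.manifest
print(f"participants: {m['participants']['enrolled']}, "
      f"valid device weeks: {m['participants']['with_valid_accelerometer']}")
print(f"EMA diaries: {m['ema']['completed_assessments']}/"
      f"{m['ema']['possible_assessments']} ({m['ema']['completion_pct']}%)")
ag = res.agreement.query("intensity == 'mvpa'").set_index("instrument")
for inst in ("ema", "brfss", "ipaq"):
    r = ag.loc[inst]
    print(f"{inst:>6} vs device MVPA: n={r['n']:.0f}  rho={r['spearman_rho']:.2f}  "
          f"LCC={r['lcc']:.2f} [{r['lcc_ci_low']:.2f}, {r['lcc_ci_high']:.2f}]  "
          f"BCF={r['bcf']:.2f}")
```

prints

```
participants: 238, valid device weeks: 193
EMA diaries: 1558/1666 (93.5%)
   ema vs device MVPA: n=193  rho=0.70  LCC=0.60 [0.51, 0.67]  BCF=0.86
 brfss vs device MVPA: n=193  rho=0.33  LCC=0.04 [0.03, 0.06]  BCF=0.12
  ipaq vs device MVPA: n=193  rho=0.25  LCC=0.04 [0.01, 0.06]  BCF=0.15
```

Read: of 238 simulated participants, 193 wore the device ≥ 10 h on ≥ 4
days and enter device comparisons (complete-case); diary completion is
93.5% of the 1666 possible daily assessments. The diary tracks the device
far better than the retrospective questionnaires — higher rank correlation
(ρ 0.70 vs 0.33/0.25) and far higher concordance (LCC 0.60 vs 0.04), with
the questionnaires' low accuracy (BCF ≈ 0.1) reflecting their built-in
multiplicative over-reporting. `res.overreporting` quantifies that bias as
a difference of cohort means: here +30 min/week of MVPA for the diary
against several hundred for the questionnaires.

The same run is available from the shell, writing the full CSV report
bundle (descriptives, correlations, agreement, Bland–Altman and
concordance plot coordinates, manifest — see `docs/data_dictionary.md`):

```bash
pa-concord all --seed 7 --out report/
pa-concord simulate --config cfg.yaml --out cohort/    # or stage by stage
pa-concord process  --epochs cohort/epochs.csv --surveys cohort/ --out proc/
pa-concord compare  --estimates proc/estimates.csv --out report/
```

Identical config + seed gives a byte-identical bundle.

## Layout

```
src/paconcord/
  synthetic.py       cohort generator + ground truth
  accelerometry.py   nonwear, cut points, daily/weekly summaries
  instruments.py     EMA / BRFSS / IPAQ / screen-time scoring
  agreement.py       Spearman, Holm, Lin's CCC, Bland-Altman
  pipeline.py        orchestration, descriptives, report tables, manifest
  cli.py             pa-concord simulate | process | compare | all
docs/methods.md      model, parameters, design choices, limitations
docs/data_dictionary.md  every CSV column
```
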