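# abpsurge

Analysis pipeline for **ambulatory blood pressure monitoring (ABPM)** data
from exercise-training trials, built around the design of isometric
resistance-training / detraining studies in young normotensives: two groups
(training-detraining, control) measured at baseline, after training and
after a detraining period, with 24-h recordings sampled every 30 min while
awake and hourly during sleep.

It is aimed at exercise physiologists and biostatisticians who need the
whole chain — raw cuff readings and sleep diaries in, group-level inference
out — reproducible and testable, plus a calibrated synthetic cohort
generator for power studies and estimator validation when participant-level
data are unavailable.

## What it computes

For each recording (diary-defined windows; QC: ≥ 80% valid readings, no
gap > 60 min):

- 24-h / daytime / night-time SBP and DBP means, nocturnal dip
  `100·(day − night)/day`;
- **sleep-trough morning BP surge**:
  `MBPS = mean(SBP in 2 h post-wake) − mean(trough set)`, the trough set
  being the lowest nocturnal reading and its smaller adjacent neighbour
  (3-reading and single-lowest variants available);
- **average real variability**, time-weighted by default:
  `ARV = Σ wₖ|xₖ₊₁ − xₖ| / Σ wₖ`, pairs never spanning the day/night
  boundary for windowed ARV;
- resting BP from measured triplets (per-channel minima, MAP recomputed).

For the cohort: split-plot (2 group × 3 time) repeated-measures ANOVA with
Bonferroni-adjusted within- and between-group post hocs, ICC(2,1) and
within-subject CV% day-to-day reliability, and exact noncentral-t sample
size for a two-sample t design (d = 1.33, α = 0.05, power 0.80 → total
n = 20).

## Worked example

Run the numbered analysis scripts (each writes its tables under `results/`):

```sh
python analysis/01_simulate_cohort.py      # 25 subjects x 3 visits
python analysis/02_qc_and_metrics.py
python analysis/03_group_inference.py
```

The inference step prints the training-arm changes from baseline:

```
training-arm changes from baseline (Bonferroni-adjusted p):
  mean_24h_sbp    mid    -8.38 mmHg  p=0.000 *
  mean_24h_sbp    end    -6.51 mmHg  p=0.001 *
  mean_night_sbp  mid    -2.00 mmHg  p=0.278
  mbps            mid    -8.95 mmHg  p=0.008 *
  arv_24h_sbp     mid    -2.37 mmHg  p=0.001 *
```

i.e. on this single simulated cohort the pipeline finds the programmed
pattern: a large, significant 24-h SBP reduction after training that is
retained (slightly attenuated) after detraining, significant MBPS and ARV
reductions, and no night-time change. `analysis/05_effect_recovery.py`
replicates this over 200 cohorts and compares the across-seed means with
the programmed effects:

```
quantity      mean    sem  median  programmed   bias  within_3_sem
d24_mid     -8.028  0.082  -8.010       -8.00 -0.028          True
d24_end     -6.032  0.072  -6.001       -6.00 -0.032          True
dnight_mid  -1.098  0.093  -1.066       -1.00 -0.098          True
dmbps_mid   -5.896  0.150  -6.008       -6.00  0.104          True
darv24_mid  -2.161  0.036  -2.150       -2.16 -0.001          True
```

`analysis/04_reliability_and_power.py` adds day-to-day reliability
(simulated CV 2.3–2.5%) and the sample-size table. The same machinery is
scriptable via the CLI (`abpsurge simulate | metrics | analyze | run |
report`) or the library API:

```python
from abpsurge import default_config, simulate_cohort, metrics_table, mixed_anova
```

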