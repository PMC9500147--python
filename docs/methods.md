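# Methods

This note documents the models, estimators and numerical choices behind
`abpsurge`: a pipeline for ambulatory blood pressure monitoring (ABPM) data
from 2-group (training-detraining vs control) × 3-visit (baseline /
post-training / post-detraining) trials, together with the synthetic cohort
generator used to exercise it.

## Windows and quality control

Daytime and night-time are diary-defined, not fixed clock windows: daytime
is the half-open interval `[wake, bed)` of the self-reported monitoring day,
night-time its complement within the nominal 24-h window (a reading taken at
the bed-time minute is nocturnal; readings before the first waking are
nocturnal). The half-open convention avoids double counting and is the only
arbitrary choice — the boundary readings themselves are rare.

A recording is discarded when fewer than 80% of the scheduled readings are
valid or when an hour of data is missing. The expected count is derived from
the diary durations and the nominal cadence (every 30 min awake, hourly
asleep: `floor(day/30') + floor(night/60')`, 40 for a 16-h day), not from
the device file, so the 80% rule is comparable across subjects. "Missing
hour" is operationalised as any gap > 60 min between consecutive valid
readings; the rule is schedule-independent and, with hourly night sampling,
is deliberately strict — a single lost night reading fails the recording.
Implausible readings (SBP ≤ DBP) are retained but flagged invalid so QC
counts reflect the device record.

## Per-recording statistics

* **Window means** — arithmetic mean of valid readings per window.
* **Resting BP** — per-channel minimum over a measured triplet; MAP is
  recomputed as `DBP + (SBP − DBP)/3` from the selected pressures (per-channel
  minima rather than the lowest-SBP reading as a unit; the triplet protocol
  does not dictate either).
* **Sleep-trough morning BP surge (MBPS)** — mean of the valid SBP readings
  in the 2 h after waking (nominally four; a warning flags any other count)
  minus the mean of a nocturnal trough set. The default `lowest2` trough rule
  is the two-reading set: the lowest nocturnal reading plus its
  smaller-valued time-adjacent neighbour (earlier on a value tie);
  `kario3` (lowest ± both neighbours) and `lowest1` (single lowest) are
  options. No normalisation to the 24-h mean. At group-mean level the
  morning-minus-lowest arithmetic is the `lowest1` rule.
* **Average real variability (ARV)** — mean absolute successive difference.
  The default is time-weighted, `ARV = Σ w_k |x_{k+1} − x_k| / Σ w_k` with
  `w_k` the inter-reading interval, which equals the unweighted form exactly
  when gaps are equal. Pairs are taken within a window only: day/night ARV
  never differences across the wake or bed boundary (night readings recorded
  before the first waking form their own run), while 24-h ARV uses all
  successive pairs. For iid noise of SD σ around a locally flat profile,
  `E[ARV] = 2σ/√π` — the identity used both as a test oracle and to invert
  observed ARVs into noise SDs.
* **Nocturnal dip** — `100·(day − night)/day` on SBP means.

## Inference

Per metric, a classical split-plot ANOVA: group is tested against
subjects-within-groups, time and group × time against the within-subject
residual (delegated to `pingouin.mixed_anova`; verified against a direct
projection/sums-of-squares oracle to 6 significant figures). With one group
the design collapses to one-way repeated measures. With three time levels
the Greenhouse–Geisser epsilon is reported, but inference defaults to the
uncorrected F. Post hocs are Bonferroni within families of three: the three
time pairs within each group (paired t) and the between-group contrast at
each timepoint (two-sample t), with adjusted p capped at 1.0. Subjects
missing any visit are listwise-deleted before the ANOVA (the classical
balanced analysis, not a mixed model). Parallel metrics (SBP, DBP, ARV,
MBPS) are not multiplicity-adjusted across measures.

Day-to-day reliability uses ICC(2,1) — two-way random effects, absolute
agreement, single measurement — plus the within-subject CV,
`100·sqrt(Σd_i²/2n)/grand mean` over paired differences. Sample size for a
two-sided two-sample t test is the smallest integer n per group whose exact
noncentral-t power (noncentrality `d·√(n/2)`, df `2n − 2`) reaches the
request; at d = 1.33, α = 0.05, power 0.80 this gives 10 per group (total
20, achieved power 0.803).

## The synthetic cohort

Each subject-visit is drawn from a smooth parametric circadian profile,

    SBP(u) = L_n + (L_d − L_n)·S(u) − D·T(u) + A·M(u) + ε(u),

with `u` hours since waking; `S` a logistic day indicator (scale 0.1 h,
≈26-min 10–90% width, centred 15 min before the wake and bed times so the
boundary readings sit on their own side); `T` a Gaussian nocturnal trough
(centre 03:30, SD 1 h, depth D = 8 mmHg); `M` a Gaussian morning bump
(centre wake + 45 min, SD 40 min); and iid reading noise ε with separate
day/night SDs. DBP shares the shapes with its own levels; heart rate is a
day/night step. The profile is deliberately not a cosinor: day level, trough
and surge are separately controllable, so the generator writes an exact
ground-truth table (structural parameters *and* the implied pre-noise window
means — the trough bump alone puts the night window mean ≈ 2.4 mmHg below
the structural night level, so recovery tests compare against the expected
means).

Subject heterogeneity: a level intercept shared by all of a subject's visits
(SD 6.8 mmHg for SBP) plus a per-visit day-to-day shift (SD 2.4 mmHg).
The visit SD is chosen so that (i) within-subject change SDs of the 24-h
mean come out near the ±4 mmHg the reference trial reports and (ii) the
simulated day-to-day CV lands at 2.3–2.5%, matching the trial's reported
2.3–2.6%. Simulated ICCs (~0.85) run a little above the reported 0.71–0.81.
All randomness flows from one seed through per-subject substreams, so
enlarging the cohort leaves existing subjects' data bit-identical.

### Calibration

The defaults are calibrated to the reference trial's printed summary
statistics, in two stages:

1. **Linear, exact.** Window means of the noise-free profile are linear in
   `(L_d, L_n, A)` with weights given by schedule averages of the shape
   functions, so baseline levels (day/night SBP 125/110 and 126/107 in the
   two arms; DBP 67/55 and 68/57) and the day/night level shifts realising a
   programmed change in the 24-h and night-time means are solved by 2×2
   linear systems.
2. **Monte-Carlo, frozen.** The morning surge involves the sampled nocturnal
   minimum and ARV involves absolute differences — both nonlinear in the
   noise — so five scalars (baseline surge amplitude per arm; surge shift
   and noise factor per effect visit) are tuned by a seeded common-random-
   numbers fixed-point iteration against the programmed targets
   (`calibrate_mc_scalars`, 6000 pseudo-subjects, 4 iterations) and frozen
   in `calibrate.FROZEN_MC`. The 2σ/√π identity provides the starting point
   for the noise factors.

Reading-noise SDs are inverted from the trial's baseline ARVs (daytime SBP
10.84 → σ 9.61; night-time 7.92 → σ 7.02 mmHg; DBP analogous). The
programmed training-arm changes are the trial's printed values: mid-visit
24-h SBP −8, night-time SBP −1, MBPS −6, 24-h SBP ARV −2.16; end-visit −6 /
−1 / −6 / −1.88 mmHg; the control arm is null throughout.

Two tensions are inherent and documented rather than hidden. First, with 32
daytime and 8 night-time readings, the printed changes −8 (24-h), −5 (day)
and −1 (night) are mutually inconsistent under any additive shift; the
generator honours the 24-h and night-time changes (the recovery surface), so
its day-window change is ≈ −10 mmHg. Second, iid reading noise biases the
sampled nocturnal minimum ≈ 7 mmHg below the profile trough, so the printed
morning mean, lowest-night mean and MBPS cannot hold simultaneously; MBPS is
honoured, which drives the calibrated morning-bump amplitudes small or
negative (+0.36 training arm, −9.20 control) while morning/lowest means stay
within a few mmHg of the printed values.

### What the generator does not emulate

Reading noise is iid (no autocorrelation, posture or activity covariates),
missingness is uniform at random (default 0 — with hourly night sampling
even 5% missingness would discard about a third of recordings through the
missing-hour rule), diaries are fixed at 07:00/23:00, and there is no
device rounding or error-mode structure. Passing recovery tests therefore
demonstrates that the estimators and inference machinery are unbiased and
correctly sized under the programmed model — not that real ABPM data meet
those assumptions.

## Problem sizes and tolerances

Effect-recovery runs use 200 replicate training-arm cohorts of 13 subjects
(≈ 18 s on one CPU); recovered means are compared to programmed values
within ±3 SEM across seeds. The type-I-error check uses 1000 null
replicates of the within-group Bonferroni family against a 99% binomial
envelope at α = 0.05. ANOVA agreement with the projection oracle is asserted
at 6 significant figures; exact identities (window partition, surge
arithmetic, Bonferroni capping, CSV round-trip) are asserted bit-exactly or
at 1e-9. Readings are serialised with `repr`/round-trip float parsing so
write→read reproduces float64 values exactly.
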