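# Methods

## Problem and endpoints

Intraoperative hypotension — mean arterial pressure (MAP) below a
clinical threshold during surgery — is associated with postoperative
myocardial and kidney injury, and monitoring platforms increasingly ship
alarm indices intended to predict it minutes ahead. This package
implements the burden-analysis pipeline used to compare two monitoring
arms on trend-level MAP exports (one sample per `nominal_interval`,
default 20 s), together with the evaluation machinery needed to probe
MAP-based prediction claims.

A **hypotensive event** is a maximal run of samples with MAP strictly
below a threshold (65 mmHg; 50 mmHg for severe hypotension) lasting
strictly more than one minute. The **primary endpoint** is the
time-weighted average of hypotension,

    TWA = (area between threshold and MAP while below it, mmHg·min)
          / (total monitoring duration, min),

in mmHg; it jointly captures depth and duration, normalised by case
length. Secondary endpoints per patient and threshold: event count,
cumulative and average event duration, percentage of monitoring time
below threshold, and the binary "any event".

## Sampling semantics and numerical choices

* The data are trend samples; sub-sample crossing times are unknowable.
  Each sample covers the half-open interval up to the next timestamp
  (the last sample covers nothing), and area uses the rectangle rule.
  A run of *k* consecutive sub-threshold samples at interval Δt
  therefore covers exactly *k*·Δt.
* "More than one minute" and "below threshold" are both strict; a run
  of exactly 60 s does not qualify, and samples at exactly the
  threshold are not sub-threshold. Runs separated by a single
  at/above-threshold sample are distinct events; there is no merge
  tolerance.
* **TWA numerator scope.** By default only qualifying (> 1 min) events
  contribute (`qualifying_events_only`), consistent with the event
  definition; `all_subthreshold_time` additionally counts sub-minute
  excursions. Both are exposed because vendor analytics conventions
  differ and exports rarely document which is used.
* **Gaps.** A gap longer than `gap_factor` (default 3) nominal
  intervals caps the preceding sample's coverage at one nominal
  interval and terminates any running event. The default denominator
  is wall clock (last minus first timestamp), treating gap interiors as
  normotensive — matching a "total duration of operation" reading; the
  `exclude_gaps` policy removes gap excess from the denominator too.
* Degenerate inputs: traces need ≥ 2 samples for event detection and a
  positive monitoring duration for TWA; empty cohorts are legal for
  filtering but not for comparison.

## Inclusion screen

Adults (age ≥ 18; the boundary age is included because the exclusion
rule is "age < 18"), elective surgery strictly longer than 120 min, no
arrhythmia impairing the pressure signal, ejection fraction ≥ 35 %, no
severe aortic/mitral stenosis. Rules are applied in a fixed order and
the exclusion report records the first violated rule per patient.

## Statistical comparison

Quantitative variables are screened with Shapiro–Wilk in each group at
α = 0.05; only if both groups look normal is the unpaired t-test used
(Welch by default — robust to unequal variances; the pooled-variance
variant is selectable), with mean ± SD summaries. Otherwise the
two-sided Mann–Whitney U test is used (exact null distribution for
tie-free samples with both n ≤ 8, normal approximation with tie and
continuity correction otherwise) with median [Q1; Q3] summaries;
quartiles use linear interpolation (the common "type 7" rule).
Proportions use the central two-sided Fisher exact test with "n (p%)"
summaries; percentage cells round half-up by default (truncation is
selectable, since published tables mix both). The per-event duration
row pools events across a group's patients by default (per-patient
means selectable). No multiple-testing correction is applied. p < 0.05
is flagged significant. Constant or empty variables degrade gracefully
(p = 1 for identical degenerate groups, n/a where one side has no
events).

## Synthetic cohort generator

No public MAP trend dataset exists for this setting, so the package
ships a generator whose defaults emulate the target population: two
arms of 61/62 patients, monitoring duration ~ Normal(241, 130²) min
truncated at 121 min, patient baseline MAP ~ Normal(85, 8²) mmHg,
within-patient fluctuation as stationary AR(1) (φ = 0.9 per 20-s
sample, innovation SD 2.5 mmHg), and hypotensive episodes from a
Poisson process (comparator arm 1.2/h vs 0.45/h), each subtracting a
raised-cosine dip whose peak takes the noise-free trace to 65 − depth
mmHg over a truncated-normal duration (means 6 vs 2.5 min; SDs 2 vs
1 min, chosen once as realistic spreads). Depths are resampled into
(0, 15) mmHg for ordinary episodes — keeping the nadir above 50 — and,
with probability `severe_fraction` (0.15 vs 0.02), drawn above 15 mmHg
(mean `depth_mean + 15`, SDs 3 vs 2 mmHg) so the nadir crosses the
severe threshold. Episodes are placed uniformly without overlap by
rejection (1000 attempts, then an error; a configuration whose episodes
would occupy > 80 % of the case is rejected outright). Truncated
normals are sampled by rejection to avoid skewing the mean under mild
truncation. One seeded RNG stream drives the whole cohort in fixed
patient order, so identical config + seed is bit-reproducible. A
`forced_episode_count` override bypasses the Poisson draw for
deterministic geometry tests.

What the generator does **not** emulate: pulse-pressure/waveform
structure, vasopressor feedback, drifts in baseline over a case,
artifacts and signal dropouts. Passing tests therefore demonstrate the
correctness and calibration of the *pipeline*, not the clinical
fidelity of any simulated effect size; the generator's group contrast
is a study-shaped emulation target, not a fit to any dataset. Note one
consequence of dips being anchored at the 65 mmHg threshold: shallow
episodes in high-baseline patients often stay sub-minute below the
threshold, so the prediction-guided arm's median TWA can be exactly 0 —
more extreme than the corresponding published medians.

## Prediction baselines and bias mechanisms

The pseudo-index `100·logistic((75 − MAP)/3)` is a strictly decreasing
transform of MAP standing in for a waveform-derived alarm index (no
proprietary algorithm is re-implemented). Its defaults place the alarm
level 85 at MAP ≈ 72–76 mmHg, matching the reported correspondence
between index alarms and MAP. Mirror structure is quantified by lagged
Pearson cross-correlation over ±10 samples (ties in the argmax broken
toward lag 0). On simulated default cohorts the event-bearing traces
show a mean lag-0 coefficient near −0.88 with best lag 0 on every
trace; individual high-baseline patients can be weaker (−0.6 to −0.8)
because the logistic saturates near 0 for MAP far above its center —
on a noiseless linear ramp all lags correlate at ≈ −1 and the argmax
lag is not meaningful.

Prediction instances anchor at every sample with a full horizon (5, 10
or 15 min) of future data; samples inside an ongoing event are
excluded (predicting ongoing hypotension is trivial and would
contaminate specificity). The label is true iff a qualifying event
starts within the horizon, so labels are monotone in the horizon.
Three scorers are evaluated: negated current MAP (alarm when MAP < 72
mmHg), the pseudo-index (alarm above 85), and a LepMAP-style linear
extrapolation — least-squares line over the last 3 min of MAP,
extrapolated to the horizon, alarming when the predicted MAP falls
below 65 (window length, first-order fit and score form are this
package's choices; all configurable). AUC is the rank statistic
(probability a random positive outscores a random negative, ties ½),
so any strictly monotone transform of MAP yields *identical* AUCs —
the mirror effect in metric form. The biased labelling rule
(`map_above_75_for_negatives`) discards negative instances with
current MAP ≤ 75 mmHg, reproducing the label-leakage critique of
published index validations; on default cohorts it inflates the
MAP-predictor's 5-min AUC by ~0.05–0.07 on average.

## Problem sizes

The heavier analyses use deliberately chosen desk-scale sizes: type-I
calibration runs 400 replicate null cohorts of 30 + 30 patients;
contrast recovery runs 50 study-sized (61/62) cohorts; the bias
inflation sweep averages 50 cohorts of 10 + 10 patients (segment sets
grow with cohort size, and the mechanism is size-independent); the TWA
integration oracle covers 200 random traces.

## Known limitations

* The event/TWA accounting assumes trend-level sampling; beat-to-beat
  waveforms are out of scope.
* The generator's AR(1)-plus-dips process has no published estimate of
  real within-patient MAP autocorrelation behind it; its parameters
  control test power, not clinical realism.
* Per-event duration pooling vs per-patient aggregation changes the
  duration row's units of inference; both are provided because
  published tables rarely state which was used.
* Proportion p-values use the central Fisher method; other two-sided
  conventions (e.g. doubling the one-sided p) can differ in the second
  decimal.
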