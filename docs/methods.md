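# Methods

`gaitspeed` estimates absolute walking speed for people with multiple
sclerosis (MS) from a single tri-axial accelerometer worn on the lower
back, using regression models calibrated per subject against supervised
clinic walks. This note documents the models, the tunable parameters, the
synthetic data the package is validated on, and the numerical choices made
where the design was genuinely open.

## Signal model and preprocessing

The device records accelerations in g in an arbitrary mounting frame.
Analysis axes are anatomical: vertical (V), mediolateral (ML) and
anteroposterior (AP).

**Tilt correction.** The gravity direction in the device frame is
estimated as the normalised mean acceleration over the analysis window
(≥ 2 s); cyclic gait accelerations average out, leaving the 1 g reaction.
No static calibration pose is required, matching how such devices are worn
in practice. A mean magnitude outside 0.5–1.5 g triggers a quality warning
(freefall/shaking). The frame is rotated so gravity maps to the vertical
axis and 1 g is subtracted.

**Horizontal orientation.** AP is the first principal direction of the
horizontal acceleration over the window; ML is the right-handed complement
`v × ap`. The AP *sign* is fixed by requiring non-negative skewness of the
AP series: trunk forward acceleration during gait is sharply peaked in the
push-off direction, so positive skewness identifies "forward". If the
horizontal principal-variance ratio is below 1.2 the orientation is
ambiguous (mostly-rest windows); a warning is raised and the rotated
device order is kept — harmless for bout detection, which uses only V and
the magnitude.

**Filtering.** A fourth-order zero-lag (forward–backward) Butterworth
low-pass at 20 Hz removes non-gait noise. The filter is the standard
digital (bilinear) design; at common device rates (100 Hz default) its
stopband is somewhat steeper than the analog magnitude formula predicts,
which only helps. Series shorter than ~3× the effective order are
rejected rather than padded.

**Bout detection.** Sliding 2 s windows (50 % overlap) are active when the
SD of the gravity-removed magnitude exceeds 0.05 g *and* the dominant
frequency of V lies in 0.5–3.0 Hz (the locomotor band). Active runs are
merged, gaps < 1 s bridged, and bouts shorter than 5 s discarded. All four
thresholds are configuration; the defaults sit inside published
free-living gait ranges. Window granularity means bout edges carry ±2 s
uncertainty, and brief (< ~3 s) movements can surface as minimum-length
bouts; the per-step analysis downstream is insensitive to edge rest.

## Step segmentation and features

Foot contact is marked by the peak of forward acceleration followed by the
AP signal's positive-to-negative zero crossing. Boundary finding runs on a
3 Hz-smoothed copy of AP (zero-crossing rules are unstable at 20 Hz
bandwidth); the smoothed copy is never used for features. Candidate peaks
need height ≥ max(0.03 g, 0.5 × median candidate height in the bout);
intervals between consecutive boundaries outside 0.2–2.0 s are discarded.

Each step yields **29 features**, computed from the 20 Hz-filtered V/ML/AP
channels: step duration; per-channel mean, SD, min, max, demeaned RMS and
range (18); AP peak value and its relative timing; signal magnitude area;
vertical displacement amplitude (range of the twice-integrated demeaned V,
with the intermediate velocity demeaned to bound drift); the three
pairwise channel correlations (defined as 0 for numerically
zero-variance channels); the dominant AP frequency and the normalised
spectral entropy of the magnitude, both over a 4 s window centred on the
step (short steps alone have too little frequency resolution); and the
RMS jerk of the magnitude. The set spans the temporal, statistical and
spectral families used in actigraphy gait analysis; its exact composition
is this package's declared contract (persisted models carry the ordered
name list and refuse mismatched feature sets).

## Calibration models

Per-step features map to speed via ε-insensitive support vector regression
with an RBF kernel. Features are z-scored with training means/SDs.
Hyperparameters are selected over C ∈ {0.1, 1, 10, 100},
ε ∈ {0.01, 0.05, 0.1} m/s and γ ∈ {1, 0.3, 3} × 1/(29 · Var(X)) by
*grouped* cross-validation minimising pooled held-out per-step RMSE, then
the winner is refit on all steps. Groups are walks for personalized models
(steps within a walk share a label, so step-level folds leak) and subjects
for the generic model. Each step's label is its walk's measured
distance/time speed — the only ground truth the supervised protocol
provides. Ties in the grid break deterministically by grid order, and
training rows are canonically sorted first, so fitting is reproducible
regardless of input order. Bout speed is the unweighted mean of step
predictions, clipped at zero.

The generic (healthy-reference) model pools calibration steps from 7
healthy walkers, subsampling each subject to ≤ 150 steps so the long
two-minute walks do not dominate the pool. Models persist as
self-describing JSON (standardisation, kernel parameters, support vectors,
dual coefficients, CV report, metadata); prediction from a loaded model
re-evaluates the RBF expansion directly and is tested against the fitting
library's own decision function.

## Home monitoring

Detected bouts with predicted distance (speed × duration) ≥ 7.62 m (25 ft)
whose start lies in the daytime window (default 07:00–22:00 local,
configurable) count as *sustained walks*. The summary reports the maximum
sustained speed over the whole observation and the mean over all sustained
walks, plus a per-calendar-day table. Distance is speed × duration — the
gate is a minimum-distance filter, not an odometer.

## Synthetic data: what it emulates, and what it does not

The simulator generates the full study design: a 32-subject cohort (20
low / 6 moderate / 6 high disability; EDSS sampled per group and mapped
linearly to a disability index d ∈ [0, 1]), a 7-subject healthy reference
group, supervised calibration sessions (8 × 25-ft walks at ±8 % trial
noise, 2 × 120 s walks, one 60 s validation walk — a desk-scale stand-in
for the longer supervised free walk) and multi-day home recordings with
ground-truth walk logs.

Gait is a phenomenological sinusoid mixture, not biomechanics. Cadence
follows f = c0 + c1·v with c0 = 1.2 + 0.8 d Hz and c1 ≈ 0.9 Hz/(m/s):
disabled walkers take faster, shorter steps at a given speed. Channel
amplitudes scale with v·f through gains that fall with d (kV = 0.35(1−0.4 d),
kAP = 0.25(1−0.3 d) g·s/m, ±15 % between subjects); step timing jitter
σT = 0.02 + 0.08 d; ML oscillates at stride frequency f/2. The AP waveform
`sin θ + 0.3 sin(2θ − π/2)` per step guarantees exactly one positive peak
followed by one positive-to-negative zero crossing (the detector's
premise) and has positive skewness (making the AP sign rule well posed).
Preferred speed is ~N(1.6 − 1.2 d, 0.08) m/s clipped to [0.4, 1.7],
matching the 0.4–1.7 m/s clinic range across EDSS 1–6. Recordings add a
fixed random mounting tilt (5–30°) and 0.02 g sensor noise. Home walks
(10–40/day, 5–120 s) draw speeds multiplicatively around the preferred
speed, truncated just above it (×1.06): sustained home maxima sit at or
just below the clinic pace, the empirical pattern that makes the clinic
test predictive of home walking. Home recordings are written sparsely —
idle periods appear as timestamp gaps that the resampler turns into
segment breaks.

Consequently, passing tests show that the pipeline recovers what this
waveform family encodes (cadence/amplitude structure, orientation
invariance, bout timing) and that the modelling logic behaves as designed
(personalized accuracy, generic-model overestimation growing with
disability, step-feature separation by disability in PCA space). They do
not certify performance on real recordings, which contain non-gait
activity, turning, asymmetry, device micro-movement and pathology-specific
waveform detail the simulator deliberately omits.

By construction the generic model's failure is *stronger* here than in the
study it emulates (cohort-level generic correlation near zero rather than
~0.85), because the synthetic cadence–speed confound is unmitigated by the
many secondary cues real accelerometry carries. The monotone error pattern
and the personalized/generic ordering are the reproduced findings; the
generic model's absolute error magnitudes are not.

## Numerical choices and degenerate inputs

- Sampling: default 100 Hz (a typical device configuration), minimum
  50 Hz (> 2 × the 20 Hz cutoff). Resampling is linear per segment; gaps
  > 1 s are never interpolated across.
- Reading CSVs parses floats through correctly-rounded string conversion,
  so write→read round trips are value-exact at repr precision.
- SD convention is sample SD (n − 1) in all reported statistics;
  Bland–Altman limits are bias ± 1.96 SD of (estimate − reference).
- PCA z-scores columns, drops constant ones with a warning, and fixes each
  component's sign so its largest-magnitude loading is positive.
- EDSS groups: low 1.0–3.5, moderate 4.0–5.5, high ≥ 6.0; out-of-scale
  scores fall to "low" with a warning.
- The clinic reference table's printed speeds mostly follow
  7.62 m / mean time rounded to one decimal; five rows print 0.05–0.06 m/s
  high, consistent with per-trial speed averaging. The package implements
  7.62/mean-time and documents the deviation. Likewise the clinic-vs-home
  correlation on the *printed* (rounded) pairs is 0.92; on unrounded data
  the study reported 0.89.
- Walks yielding < 2 steps are excluded from training with a warning;
  fitting requires ≥ 30 labelled steps over ≥ 2 distinct speeds.

## Problem sizes

Defaults are desk-scale by design: 100 Hz recordings, 60 s validation
walks, 1–3 home days per subject, and the 32 + 7-subject cohort for the
study-level comparison (≈ 1 minute end to end on one core). All sizes are
arguments; nothing in the code assumes them.
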