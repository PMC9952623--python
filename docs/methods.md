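# Methods

This note documents the models, algorithms and design choices behind
`ctgkit`, and what the synthetic experiments do and do not demonstrate.

## Record model and quality screening

A CTG record is an evenly sampled FHR series (default 4 Hz, i.e. a 0.25 s
step — the same step the spectral stage resamples to, so the whole pipeline
shares one clock) with optional uterine-activity channel. Missing samples
are encoded as 0 bpm in files. In memory a sample is invalid when it is the
sentinel, outside the physiological range 50–240 bpm, or an isolated spike
(> 25 bpm away from both neighbours). The spike rule is conventional
artifact rejection for Doppler-derived FHR; it deliberately does not reject
step changes, which are handled by the baseline stage.

Eligibility (antepartum week 36–40, duration > 20 min, signal loss < 30%,
outliers < 5%, singleton) is a predicate, not a filter: ineligible records
load and analyse normally and simply carry `eligible=False`. Signal loss
counts sentinel samples; the outlier percentage counts measured samples
rejected by the screen, so the two are disjoint and each is an exact count
ratio.

Invalid runs are filled by linear interpolation between flanking valid
samples (nearest-value extension at the edges). Runs longer than 15 s are
flagged `long_interp`; events overlapping such runs are reported but marked
invalid, and STV windows containing them are discarded. Linear filling is
the least-commitment choice: it adds no spectral content of its own, and
the long-run flag bounds how much fabricated signal can influence any
downstream statistic. Interpolation is idempotent and never leaves the
convex hull of the flanking values.

## Baseline and floating line

The baseline must ignore transient events but follow sustained level
shifts. We use an iterative trimmed running median: a 10-min centred
running median, then three iterations in which samples further than 15 bpm
from the current estimate are replaced by it before re-filtering. A median
over 10 min is unmoved by events of a few minutes, while plateaus longer
than half the window (tachycardia/bradycardia by definition) are tracked
with edge positions preserved — a step plateau of duration D longer than
the window reappears in the median with duration ≈ D, which is why injected
arrhythmia durations are recovered to within a few percent.

The floating line is a 2-min running median of the full signal: long enough
to be insensitive to beat-to-beat variability, short enough to track
through accelerations and decelerations, so that FHR − floating line
isolates the variability signal.

## Event and arrhythmia detection

Accelerations/decelerations are excursions of the interpolated FHR from the
baseline. Detection is a Schmitt trigger: a run is delimited where the
excursion exceeds threshold − 5 bpm (10 bpm by default) but must reach the
full ±15 bpm somewhere inside. Without hysteresis, beat-to-beat variability
of 2–3 bpm fragments a genuine 20 bpm excursion into sub-15-s pieces;
the 5 bpm band is ≈ 2 SD of typical short-term variability. Duration rules:
valid accelerations last ≥ 15 s and < 10 min (longer counts as a baseline
change); decelerations ≥ 15 s, prolonged beyond 3 min.

Arrhythmia recognition runs per-sample on the baseline vector. Comparisons
are strict (> 160, < 110 bpm — a plateau exactly at threshold does not
qualify) and the duration rules mirror the clinical wording: tachycardia
*at least* 10 min (inclusive), bradycardia *more than* 3 min (exclusive).
Invalid stretches break a run. Severe tachycardia is a run whose mean
exceeds 180 bpm.

## STV

STV is the sample standard deviation (n−1 denominator) of the FHRV signal
on non-overlapping 30-s windows; the record-level index is the mean over
good-quality windows (< 50% interpolated samples, no long-interpolation
overlap; the trailing partial window is dropped). Non-overlapping tiling
keeps windows independent; the hop is configurable for overlapped variants.
STV below 0.02 bpm is additionally flagged as clinical absence of
variability. STV is translation-invariant, absolutely homogeneous, and
per-window equal to a two-pass variance computation to 1e-9 relative.

## Spectral analysis

The PSD estimator is a frame-averaged modified periodogram (Welch-type):
32-s Hanning frames at 0.25-s sampling, 50% overlap, 1024-point FFT, each
frame normalised by L·U with U the mean squared window, and an extra 1/fs
to yield a one-sided density in bpm²/Hz so the frequency integral obeys
Parseval. Frames are mean-subtracted: the FHRV input is already detrended
by the floating line, and removing the residual per-frame offset keeps the
VLF band from being dominated by numerical DC. With a rectangular window
and one full-length frame the estimator reduces to the plain periodogram
(verified against an independent Welch implementation at identical
settings).

Band powers are trapezoidal integrals over VLF 0–0.05, LF 0.05–0.2 and
HF 0.2–1 Hz, with the band edges interpolated onto the frequency grid so
adjacent bands tile the axis exactly (band powers sum to the 0–1 Hz
integral). Total power is VLF+LF+HF and SVB = LF/HF; a zero HF power makes
SVB undefined (`None`), never infinite, and annotation treats that as
maximally non-reactive. Resampling to the 0.25-s grid, when needed, is
cubic-spline.

## Annotation

Six alarm bits in fixed order (BRAD, TACH, ACC, DEC, STV, SVB): episode
counts for BRAD/TACH, *absence* of valid accelerations for ACC, prolonged
decelerations for DEC (the alarm list concerns prolonged ones; a flag
switches to any deceleration), and strict `<` cut-offs STV 1.70 and SVB
8.20. Criterion 1 ("no accelerations and at least one alarm") is read as
requiring one alarm *besides* the ACC bit, which the ACC bit itself would
otherwise always satisfy; this matches the published worked example, where
the SVB bit supplies the second alarm. The reading is configurable. The
labelling is pure; a second verification pass is asserted identical.

## Classification

The SVM is scikit-learn's SVC behind a thin interface; the evaluation
scheme and metric suite are implemented here. Stratified 10-fold CV with a
fixed shuffle seed (plain k-fold when folds exceed the minority class,
e.g. leave-one-out); z-score standardisation is fitted on training folds
only. Hyperparameters are declared, not tuned: C = 1, RBF/poly gamma =
"scale". The *normal* class is positive. Metrics are reported both from the
pooled confusion matrix over all held-out predictions (the default report —
a printed confusion matrix corresponds to pooling) and as means of
per-fold metrics. Undefined ratios (0/0) are NaN markers, never infinities.
Aggregation note: exact weighting of exact per-class values can differ in
the last printed digit from weighting already-rounded cells (e.g. weighted
precision 92.153 exact vs 92.12 from one-decimal inputs).

## Synthetic generator

Records are sums of interpretable parts: baseline level (plus trapezoidal
arrhythmia shifts with 30-s ramps), trapezoidal events with 5-s ramps,
Gaussian noise low-pass filtered at 0.08 Hz and rescaled to an exact target
SD, LF (0.1 Hz) and HF (0.4 Hz) sinusoids whose amplitude ratio sets the
spectral balance, bell-shaped uterine contractions, plus masked gaps
(exponential lengths, mean 4 s, capped at 12 s) and isolated out-of-range
outliers. All randomness flows from one seed; cohorts draw child seeds from
a root generator so each member is independently reproducible.

Cohorts emulate an antepartum screening population of 30-min traces.
Normal draws mix four sub-families — classic reactive, borderline-STV,
borderline-SVB and rest-state (no accelerations, otherwise reassuring) —
where borderline draws are marginal in exactly *one* index, so a single
alarm bit can never flip the intended label and class counts stay exact.
Suspicious draws sample five archetypes covering the four criteria:
non-reactive (no accelerations, low SVB), low-variability (no
accelerations, low STV), criterion-2 (accelerations retained but STV and
SVB both low), severe tachycardia (12–15 min above 183 bpm) and bradycardia
(8–12 min below 105 bpm). The intended label is derived by applying the
annotation rules to the generating parameters through small-signal proxies
(intra-window noise fraction ≈ 0.75 of the total SD; the low-passed noise
contributes ≈ 45% of its power to LF and ≈ 2% to HF); archetypes keep
comfortable margins from the cut-offs wherever the proxy decides the label.

What the generator does *not* emulate: autonomic coupling between
contractions and decelerations, sinusoidal pathological patterns,
gestational-age dependence of the indices, or monitor-specific artifact
structure. Passing end-to-end tests therefore demonstrates the internal
consistency of the pipeline (detection recovers what was injected;
annotation matches generating intent; the classifier separates
rule-consistent classes), not clinical performance on real traces.

## Problem sizes and determinism

Default experiment sizes: 30-min records at 4 Hz (7,200 samples), cohorts
of 50 records, 1,000 random baselines for the arrhythmia equivalence
check. One balanced + one imbalanced screening experiment runs in ~5 s on
one core. Stochastic assertions (Monte-Carlo STV consistency, Parseval on
white noise, the screening experiment) use fixed seeds; the balanced-vs-
imbalanced G-mean ordering is a stochastic effect that holds for the
default seed and the large majority of nearby seeds, with ties possible
when both cohorts are classified perfectly.

## Known limitations

* The baseline estimator smears arrhythmia onsets by up to ~half a trend
  window when the plateau is shorter than the window; episodes shorter than
  ~5 min may be attenuated below threshold.
* Dips shorter than the 2-min floating-line window leak partially into the
  FHRV signal and hence into STV.
* The uneven (beat-to-beat) STV variant for true RR series is out of scope;
  the evenly-sampled branch is implemented.
* Deceleration sub-typing (early/late/variable) and three-class
  (pathological) labelling are out of scope.
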