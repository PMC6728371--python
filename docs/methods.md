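# Methods

`icualarms` classifies life-threatening bedside-monitor arrhythmia alarms as
true or false from the waveforms alone.  An alarm record is a 300-s,
250-Hz multi-channel recording (two ECG leads, optionally a
photoplethysmogram and/or an arterial-pressure line) with the alarm raised
at the 300-s mark for one of five conditions: asystole, extreme
bradycardia, extreme tachycardia, ventricular tachycardia (VT) or
ventricular flutter/fibrillation (VF).  The pipeline has three stages —
signal screening and beat detection, feature extraction, cost-sensitive
random-forest classification (with a rule-based classifier for
bradycardia) — plus a synthetic alarm generator that serves as the test
bed.

## Signal screening

*Flat lines.*  A segment that holds an exactly constant value for at least
2 s is treated as probe disconnection and masked; the 2-s duration is the
published rule, the zero amplitude tolerance is ours (disconnection
produces exactly repeated samples; configurable).  Only the flat span is
masked, not its surrounding window: the features that matter near an alarm
live in the final seconds, and discarding a whole window for a brief
disconnect earlier would throw away usable evidence.

*ECG baseline wander* is removed per analysis window by subtracting a
least-squares polynomial of order 5.  The operator is linear and
annihilates polynomials up to that order, so tests can assert both
properties exactly.

*Arterial-pressure screening* flags abnormal beats using beat-morphology
criteria: systolic > 300 mmHg, diastolic < 20 mmHg, mean pressure outside
30–200 mmHg, pulse pressure < 20 mmHg, mean negative slope steeper than
−40 mmHg per 100 ms, beat-to-beat systolic or diastolic jumps > 20 mmHg.
Heart-rate-range and period-change criteria are implemented but disabled
by default, since rate excursions are exactly what the arrhythmia features
must see.  All thresholds live in `PreprocessConfig`.

## Beat detection

*QRS detection* uses an undecimated à-trous filter bank with the
quadratic-spline pair (lowpass `[1,3,3,1]/8`, highpass `[2,−2]`), four
dyadic scales, delay-compensated.  The wavelet behaves as a smoothed
differentiator: a QRS produces a positive/negative modulus-maxima pair
whose zero crossing marks the R peak.  Detection runs on
`|W2|+|W3|` with a threshold at 0.3 of the 99th percentile of that trace
over the analysis segment, a 0.2-s refractory period (300 bpm ceiling),
and a search-back at half threshold inside RR gaps longer than 1.75× the
median.  Because all thresholds are relative, detections are invariant to
amplitude scaling and constant offsets.  Beat amplitude is recorded as
half the peak-to-peak wavelet excursion of the pair — offset-invariant and
proportional to the physical amplitude, which is what the peak-height
stability index needs.

*Pulse onsets* on BP/PPG: the slope sum function (SSF, trailing 128-ms sum
of positive first differences) applied twice, with no pre-filtering, turns
each upstroke into a sharp bump while ignoring baseline drift; the same
wavelet peak detector locates the bumps on a lightly smoothed trace.  The
onset is then placed where the steepest-ascent tangent of the bump meets
its local baseline.  We chose the tangent construction over a fixed
group-delay correction because the SSF bump peak lags the onset by roughly
the pulse rise time, which varies; the tangent intersection tracks the
start of the upstroke regardless of rise time.  On the synthetic test bed
this recovers onsets within a few tens of milliseconds and leaves recovery
unchanged under sinusoidal wander of full pulse-pressure amplitude.

*False-peak rejection* uses band-limited amplitude envelopes (defaults:
low 0.5–6 Hz, QRS 5–25 Hz, high 30–90 Hz; rectify-and-smooth over 0.1 s).
A detection whose high-band envelope exceeds 0.7× its QRS-band envelope is
a pacing spike (broadband impulse); one whose QRS-band envelope falls
below 0.3× the median over remaining beats is an over-sensed T wave.
A beat is flagged ventricular when its low-band envelope exceeds 0.2× the
QRS-band envelope while the high band stays low: widening a complex from
~80 ms to ~160 ms moves its spectral mass from roughly 12 Hz down to
6 Hz, which this ratio detects far more reliably than measuring envelope
width directly (bandpass ringing makes widths of narrow and wide
complexes nearly indistinguishable).  The constants were calibrated on
the synthetic waveforms and are all in `DetectConfig`.

## Features

Every channel role (`ecg1`, `ecg2`, `ppg`, `abp`) contributes a
signal-quality block — beat-template correlation, peak-height stability
(fraction of beats within ±30% of the median |amplitude|), peak sharpness,
periodicity (peak unbiased autocorrelation over lags 0.24–2.4 s) — and a
swing block (min/max/mean of per-second peak-to-peak swing).  Per
arrhythmia the registry adds: maximum RR interval and blank-area swing
(asystole); minimum 5-beat and slowest 4-beat rate (bradycardia); maximum
17-beat rate (tachycardia); spectral mean/median frequency and maximum
single-bin power share over 0.5–15 Hz on ECG (VF); ventricular-run length,
ventricular-run rate and mean envelope width on ECG (VT).  Registry sizes
land between roughly 20 and 40 features per arrhythmia.  Missing channels
leave NaN columns; forests impute them with training-fold medians.

Run rates use 60·(n−1)/(t_n−t_1).  The maximum RR interval counts the
window edges as virtual beats so a beat-free asystole window yields the
full window length.  Blank-area swing measures the waveform excursion
inside the longest beat-free span, trimming 0.5 s after the preceding beat
and 0.25 s before the next so T and P waves stay outside the "blank" area.

Analysis windows (seconds before the alarm): asystole 16, bradycardia 20,
tachycardia 20, VF 16, VT 10 — our defaults, configurable.  Each record
contributes one feature vector, except true-VF alarms during training,
which contribute four (window starts 293–296 s, each running to the
alarm): the standards-mandated alarm latency means the triggering 4 s of
fibrillation may start anywhere in that range.

The spectral estimator is a hann-tapered periodogram of the mean-removed
window.  Under the taper a pure bin-centered tone concentrates exactly 2/3
of band power in its peak bin; the VF/artifact contrast (≈0.25 vs ≈0.1 on
the generator) is unaffected by the taper choice.

## Classifier

`CostSensitiveForest` is a scikit-learn-style estimator: 301 bagged CART
trees, Gini splits, sqrt-of-features candidates per split, majority vote.
The class prior is uniform (each class weighted inversely to its
frequency) and asymmetric misclassification costs multiply those weights —
cost_FP fixed at 1, cost_FN tuned on a 1.0–2.0 grid in 0.1 steps by
record-grouped leave-one-out cross-validation (LOOCV), ties to the
smallest cost.  The grid is a superset of the 1–1.4 range where the
optimum is expected to land.

Feature importance follows the TreeBagger recipe: per tree, the OOB error
increase when one feature is permuted across that tree's out-of-bag rows;
the mean over trees divided by the standard deviation over trees.  A
constant feature scores exactly zero (permutation is a no-op).

Forward selection ranks features by that importance and scores top-k
prefixes with LOOCV at k values that are dense for small k and
geometrically spaced above (at most 8 points) — the curve's plateau, not
its fine structure, is what matters.  The whole procedure runs five times
with fresh seeds; the plateau point x is the smallest k whose median score
is within 0.5 score units of the best median, and the final set keeps
⌈1.2·x⌉ features, then adds the `ecg2` twin of every selected `ecg1`
feature and vice versa so both leads contribute symmetrically.

Inside the selection and cost-tuning loops the forests use 21 trees; the
final model is always trained on all rows with 301.  The small selection
forests only rank features and locate a plateau, tasks that tolerate vote
noise, and they keep the ~n_records × k-grid × repeats × grid LOOCV
refits tractable on one core.  Within each LOOCV fold all rows of a record
(the four augmented VF rows) are held out together — splitting them would
leak the record into its own test fold — and the held-out record's
prediction is the mean positive-vote fraction over its rows.

*Bradycardia* bypasses the forest: the channel with the highest
beat-template correlation in the window is selected as most reliable, and
the alarm is true iff its slowest 4-consecutive-beat rate is strictly
below 46 bpm.  "Slower than 46" is read as a strict inequality; a record
with fewer than 4 usable beats, or no usable channel, defaults to a true
alarm, because missing a real extreme bradycardia costs five times a
false positive under the score.

## Evaluation

TP rate = TP/(TP+FN), TN rate = TN/(TN+FP), and
score = 100·(TP+TN)/(TP+TN+FP+5·FN), reported per arrhythmia and pooled
jointly over all records (not a mean of per-type scores).  Zero
denominators yield missing rates rather than errors.

## Synthetic test bed

The generator renders records from explicit ground-truth beat trains, so
every verdict is checkable against the definitions: no QRS for ≥ 4 s
(asystole); rate < 40 bpm over 5 consecutive beats (bradycardia);
rate > 140 bpm over 17 beats (tachycardia); ≥ 5 ventricular beats at
> 100 bpm (VT); oscillatory waveform ≥ 4 s (VF).  Durations are inclusive
boundaries, rates strict, with a 1e-9 guard against floating-point
round-off at exact boundaries.  QRS complexes are Mexican-hat templates
(~80 ms narrow, ~160 ms wide ventricular) with P/T bumps; VF is an
amplitude-modulated 4–6.5 Hz sinusoid; pulses are half-cosine upstrokes
with exponential decay (ABP scaled to ~120/78 mmHg).  Beat times snap to
the sample grid so detector fiducials can match exactly.  True alarms
embed a qualifying episode ending near the alarm; each generated record
asserts at build time that its verdict matches its label.

False alarms carry the artifact processes that fool monitors — noise
bursts, flat lines, pacing spikes, tall T waves, heavy pulse-channel
noise — chosen per arrhythmia.  For asystole/bradycardia/tachycardia/VF
the artifact lands on channels *other than* the first ECG lead (or is
broadband enough not to mimic the arrhythmia), so the lead-I features
retain the discriminating signal, mirroring the intended clinical reading
that at least one reliable channel contradicts the alarm.  False VT is the
exception: its artifact (irregular wide bumps, or a noise burst) corrupts
the analyzed ECG lead itself, because that is the only way a monitor
mistakes artifact for VT — and it is exactly what makes the correlation
SQI the discriminating feature (uniform monomorphic VT complexes correlate
near 0.87; irregular artifact near 0.3).

What the generator does **not** emulate: real QRS morphology variation,
ectopy, atrial fibrillation, electrode-motion artifact spectra, inter-channel
delays beyond a fixed 0.2-s pulse transit, or the label noise of human
annotation.  Passing tests therefore demonstrate that the implemented
operators and decision logic behave as specified under the named failure
modes — not that the trained forests would reach any particular score on
real monitor data.

## Problem sizes and determinism

The bundled benchmark trains on 100 alarms per arrhythmia (50 true/50
false; true-VF augmentation brings its table to ~250 rows) and evaluates
on a held-out 40 per type, which keeps the full train-plus-evaluate cycle
in the minutes range on a single core while leaving every class with
enough records for stable LOOCV curves.  All randomness flows from one
master seed through `numpy.random.SeedSequence` spawns keyed by component
(record index, tree index, repeat index), so every artifact — generated
records, selected features, tuned costs, predictions — is bit-reproducible
given the seed.

## Known limitations

Waveform realism is deliberately minimal (see above).  The wavelet
detector is re-implemented to the cited algorithm's structure, not
bit-compatible with any reference code.  Forest feature ranking is
computed on the full table once per repeat rather than inside every LOOCV
fold; with record-grouped folds that differ by one record the two agree up
to noise, at n-fold lower cost.  The 330-s "retrospective" record variant
is only truncated at the alarm, never analyzed beyond it.
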