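# Methods

## Detection model

The framework treats seizure detection as windowed binary classification
followed by temporal post-processing, separately per modality, with
decision-level fusion at the end.

**bte-EEG branch.** Both EEG channels are band-passed 0.5–35 Hz with a
zero-phase 4th-order Butterworth filter (zero-phase so the rhythmic ictal
pattern is not phase-distorted; the band matches what reviewers see on
screen). The signal is cut into 2 s windows with a 1 s hop; window *i*
covers `[i, i+2)` s and the last window must lie fully inside the
recording. Each window yields 67 features in four families:

| family | count | content |
|---|---|---|
| time | 11 × 2 ch | mean abs, RMS, peak-to-peak, line length, zero crossings, skewness, kurtosis, Hjorth activity/mobility/complexity, mean Teager energy |
| frequency | 9 × 2 ch | relative power in δ (0.5–4), θ (4–8), α (8–13), β (13–20), high (20–35 Hz); 95 % spectral edge; peak frequency; spectral centroid; log total power |
| entropy | 4 × 2 ch | sample entropy (m = 2, r = 0.2 SD), normalized spectral entropy, permutation entropy (order 3), SVD entropy (embedding 10) |
| asymmetry | 19 | per-band relative-power differences, log power ratios and power asymmetry indices (5 each), log RMS ratio, log line-length ratio, zero-crossing difference, max cross-correlation within ±50 ms |

The family sizes are fixed in code; the count of 67 and the four families
are contractual, and the per-feature scale- and channel-swap behaviour
(invariant/covariant, antisymmetric/symmetric) is documented in
`wearseiz.eeg_features` and asserted by tests. The window classifier is a
standardized RBF-SVM (defaults C = 1, γ = 1/n_features,
inverse-frequency class weights — seizure windows are well under 1 % of a
long recording). Training windows are labelled positive when at least
half the window overlaps a ground-truth seizure.

Post-processing keeps a detection only when at least 8 of 10 consecutive
windows are classifier-positive. A qualifying group starting at window
*g* contributes the span `[g·hop, (g+10)·hop)`; overlapping or contiguous
spans merge. This span convention makes the shortest possible alarm
exactly `10·hop = 10 s` (a literal first-sample-to-last-sample reading
would give 11 s); both the group length and threshold are parameters.

**ECG branch.** The detector never uses ECG morphology beyond beat
times. R-peaks come from a majority-vote ensemble of two detectors (a
derivative–square–integrate scheme with an adaptive threshold, and an
amplitude-adaptive local-maximum picker), clustered at 100 ms tolerance;
ensembling suppresses detector-specific false beats. Instantaneous heart
rate is 60/RR at beat midpoints after rejecting implausible RR intervals
(outside 0.24–3 s or a beat-to-beat change above 35 %, standard
HRV-cleaning practice). Seven features are computed on 60 s windows at a
10 s hop: mean HR, HR range, least-squares HR slope, RR SD, RMSSD,
pNN50, and the ratio of the window mean to the trailing 5 min baseline.
Windows with fewer than 5 beats are excluded. Because the autonomic
response lags and outlasts the electrographic seizure, training labels
are the ground-truth seizures extended by 30 s on each side (then
merged). Every positive window contributes its full 60 s span, so ECG
alarms last at least 60 s and their durations are multiples of 10 s.
The window classifier defaults to the same RBF-SVM family as the EEG
branch (a linear-SVM switch exists).

**Fusion.** 'OR' at the decision level: every EEG alarm is kept; an ECG
alarm is kept iff it overlaps no EEG alarm, and is dropped whole
otherwise (the EEG extent localizes the event an order of magnitude more
tightly). Intervals are half-open, so `[a,b)` and `[b,c)` touch without
overlapping and both survive. One consequence, exercised by a dedicated
test: a seizure covered only by the non-overlapping tail of a dropped ECG
alarm loses coverage. The alternative — truncating the ECG alarm and
keeping the remainder — was considered and not adopted, because a
truncated fragment below the 60 s minimum is no longer a well-formed ECG
alarm.

**Tachycardia response.** Per seizure, the heart-rate increase is the
maximum HR in `[start, end+30 s]` minus the median HR in the 60 s
pre-ictal window. At least 20 BPM makes a *responder*; an increase that
exceeds the baseline-wander band (default tolerance 6 BPM — the peri-ictal
maximum of a wandering baseline sits above the pre-ictal median even with
no ictal effect, and 6 BPM bounds hour-scale wander at a 2 BPM SD) but
stays under 20 BPM is *intermediate*; anything inside the wander band is
a *non-responder*. Setting the tolerance to 0 restores a strict
zero-threshold rule. Missing pre-ictal coverage gives *undetermined*.

## Event-based scoring

An alarm overlapping any ground-truth seizure (non-empty intersection of
half-open intervals, no minimum fraction) is a TP detection, otherwise an
FP; a seizure is detected when at least one alarm overlaps it. Both
counts are exposed because they differ: several alarms can hit one
seizure, so TP detections can exceed detected seizures. The report's
`sensitivity` is detected/(detected+missed); `detection_sensitivity`
(TP/(TP+FN detections)) is also provided, since published figures may be
computed either way. FD/24h = 86400·FP/D with D the scored recording
seconds; PPV = TP/(TP+FP); F1 is the harmonic mean of sensitivity and
PPV. Ratios with zero denominators are reported as NaN with the field
name flagged — never silently zero, which would corrupt stratified
tables. Reader (semi-automated review) scoring differs in one deliberate
way: readers only ever see the algorithm's alarms, so seizures with no
alarm are excluded from the reader's denominators entirely.

Cohen's κ is computed from the observed agreement and the product of the
rater marginals; when chance agreement is exactly 1 (both raters constant
on one category) observed agreement is necessarily 1 too and κ is defined
as 1. McNemar's test is exact (two-sided binomial) when the discordant
count b+c is below 25 and the continuity-corrected χ² with 1 df
otherwise; b = c returns p = 1 by symmetry, including the degenerate 0/0
case (flagged).

## Synthetic recordings

The generators emulate the statistical structure the detectors rely on,
not the underlying physiology:

* **Background EEG**: zero-mean 1/f-weighted noise, SD = `background_amp`
  (default 20 µV, a typical awake-background RMS at mastoid electrodes).
* **Ictal discharge**: a theta-range sinusoid (3–8 Hz; the cohort the
  framework targets is dominated by temporal-lobe seizures, whose
  wearable-visible rhythms sit in this band) with a linear amplitude ramp
  from 0.3× to 1× `ictal_eeg_amp` (default 50 µV) over the seizure, plus
  background-scale noise; injected at full strength on the cross-head
  channel and ×0.6 on the ipsilateral one.
* **Artifacts**: 20–35 Hz band-limited bursts (the in-passband part of
  EMG), 2–6 s long, amplitude 60 µV, at `artifact_rate` (default
  6/hour) placed outside a 30 s guard around seizures. Co-locating an
  artifact with a heart-rate rise — the classic confound for both the
  algorithm and human readers — is possible by configuring a seizure
  interval with `ictal_eeg_amp` small and `artifact_guard_s = 0`.
* **Heart rate**: 1 Hz series; baseline (default 70 BPM) plus bounded
  wander (slow sinusoids + jitter, SD ≈ 1.4 BPM, excursions < 6 BPM) and,
  per seizure, a rise of `ictal_hr_increase` ramping over 20 s, held to
  seizure end, decaying exponentially (τ = 45 s). The responder /
  intermediate / non-responder conditions use increases of 25 / 10 / 0
  BPM, straddling the 20 BPM criterion.
* **ECG**: a fixed PQRST Gaussian template stamped at beat times
  integrated from the heart-rate profile (next beat one RR = 60/HR later,
  ~5 ms timing jitter), plus 0.02 mV noise. Template synthesis was chosen
  over a dynamical ECG model deliberately: the true R-peak times are then
  known exactly and serve as ground truth for the R-peak detectors.

Everything is a pure function of (config, seed). The packaged cohort
table (42 patients, 221 seizures; 23/13/6 tachycardia yes/intermediate/no;
173 focal impaired-awareness seizures; 134 temporal) fixes the population
structure for stratified tests.

**What passing tests do and do not show.** The generators produce a
*separable* world: the ictal rhythm is spectrally distinct from both
background and artifact, and the responder heart-rate effect is clean.
Detector tests on this world verify the pipeline's plumbing, conventions
and statistical machinery — they say nothing about sensitivity on real
patients, where ictal patterns can be invisible on two channels, muscle
artifact is broadband and rhythmic, and ECG electrode noise corrupts the
R-R series. Test-cohort recordings are 900–1200 s (clinical recordings
run for days; length changes only the amount of background, and the
problem sizes keep the full suite in tens of seconds), which also means
false-alarm rates quantize coarsely: one FP in a 10×1200 s cohort is
already 7.2 FD/24h.

## Numerical choices and degenerate inputs

* EDF I/O is 16-bit; the writer picks a symmetric physical range with 1 %
  headroom (or an explicit per-role range) so the round-trip error is at
  most half a quantization step, `(phys range/65535)/2`. Data records are
  1 s, so signals must span whole seconds and integer sampling rates.
* All-zero/constant EEG windows use fixed conventions (uniform relative
  band powers, zero entropies and slopes) so feature matrices never
  contain NaN; NaN *input* raises, naming the first bad window.
* Sample entropy runs on 2× decimated windows (250 → 125 Hz, still 3.6×
  the passband edge) to keep its O(n²) cost negligible; an empty
  (m+1)-match count gets a 0.5 continuity correction instead of an
  infinite value.
* HR smoothing is a centred 7-beat moving average: unbiased on linear
  ramps and ~√7 noise reduction on independent beat-timing jitter; gross
  RR artifacts are already rejected upstream, so median robustness is
  unnecessary. With it, the full HR profile (including a 25 BPM ramp) is
  recovered from synthetic ECG within 2 BPM.
* The R-peak ensemble clusters greedily in time order with at most one
  peak per detector per cluster; the 100 ms tolerance is half the 200 ms
  detector refractory period, so clusters cannot chain.
* Alarm ids in review packages are position + modality + millisecond
  interval: stable across identical calls, unique even for duplicate
  intervals.

## Known limitations

* The 67-feature bank is *a* fixed, documented realization of the four
  stated families, not a reimplementation of any published feature list;
  likewise the R-peak ensemble preserves the ensemble contract, not any
  specific published trio of algorithms.
* Patient-specific vs patient-independent training is left to the caller
  (`fit_recordings` accepts any split); no split policy is built in.
* No online/causal operation: filtering is zero-phase and post-processing
  needs the full window sequence.
* EDF+ timed annotations (TAL), BDF, and streaming ingestion are out of
  scope; annotations travel as CSV sidecars.
* The human-review components package and score relabels; they do not
  provide a viewer, blinding management, or video handling.
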