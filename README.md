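# wearseiz

Semi-automated multimodal seizure detection for wearable recordings:
two-channel behind-the-ear EEG (bte-EEG) plus single-lead ECG.

## The problem

People with refractory focal epilepsy need seizure counts outside the
hospital, but full-scalp video-EEG does not travel and seizure diaries miss
half of all events. Wearable bte-EEG (one cross-head and one ipsilateral
channel over the mastoids) can capture focal ictal rhythms, and many
patients show *ictal tachycardia* — a peri-ictal heart-rate rise of at
least 20 BPM — that a chest ECG picks up even when the EEG pattern is
buried in artifact. Automated detectors on these signals are sensitive but
fire many false alarms, so the practical workflow is **semi-automated**:
the algorithm flags candidate events and a human reviews only those flags
(minutes per day of recording instead of an hour). This package implements
that whole loop as a tested library and CLI:

* **EEG detector** (`wearseiz.eeg.EEGSeizureDetector`) — 0.5–35 Hz
  zero-phase band-pass, 2 s windows at a 1 s hop, a 67-feature bank
  (time-domain, spectral, entropy, and cross-channel asymmetry families),
  a standardized RBF-SVM window classifier, and an 8-of-10 consecutive
  window post-processing rule. The shortest possible alarm is 10 s.
* **ECG detector** (`wearseiz.ecg.ECGSeizureDetector`) — a majority-vote
  ensemble of R-peak detectors, instantaneous heart rate HR = 60/RR with
  artifact rejection, heart-rate features on 60 s windows at a 10 s hop,
  training labels extended ±30 s to cover the slower autonomic response.
  Alarms are at least 60 s long.
* **'OR' late fusion** (`wearseiz.fuse_or`) — an alarm is raised if either
  modality fires; when alarms overlap, the bte-EEG segment is kept.
* **Event-based scoring** (`wearseiz.evaluation`) — sensitivity,
  false detections per 24 h (FD/24h = 86400·FP/D), PPV = TP/(TP+FP),
  F1 = 2·Sens·PPV/(Sens+PPV); stratification by seizure-onset localization
  and tachycardia response; Cohen's κ and McNemar's test for comparing
  readers.
* **Review workflow** (`wearseiz.review`) — packages alarms (with the
  10 s / 70 µV/cm EEG and 10 min heart-rate display settings as metadata)
  for relabelling as seizure / artifact / other, and scores the relabels.
* **Synthetic recordings** (`wearseiz.synthetic`) — seeded generators for
  bte-EEG background, ramped theta-range ictal rhythms, EMG-band artifact
  bursts, heart-rate profiles with configurable peri-ictal rises, and
  template-based ECG with exactly known R-peak times, plus a packaged
  42-patient cohort table (221 seizures; 23 tachycardia responders).
  Clinical wearable recordings are privacy-restricted, so every detector
  is developed and tested against these generators.

Detectors follow scikit-learn conventions (`fit`/`predict`/
`decision_function`, `get_params`, fitted attributes with trailing
underscores) and compose with sklearn pipelines and model selection;
`fit_recordings`/`detect` wrap the full signal-to-alarms chain.

## Worked example

```python
import wearseiz as ws
from wearseiz.synthetic import make_cohort, default_config, gen_recording
from wearseiz.eeg import EEGSeizureDetector
from wearseiz.ecg import ECGSeizureDetector, smooth_hr
from wearseiz.evaluation import match_events, compute_metrics

train = make_cohort(4, base_seed=0, duration_s=900.0)
eeg = EEGSeizureDetector().fit_recordings(
    [m.recording for m in train], [m.ground_truth for m in train])
ecg = ECGSeizureDetector().fit_recordings(
    [m.recording for m in train], [m.ground_truth for m in train])

cfg = default_config(99, duration_s=900.0)   # unseen test recording
rec, truth = gen_recording(cfg, patient_id="demo")
fused = list(ws.fuse_or(eeg.detect(rec), ecg.detect(rec)))
rep = compute_metrics(match_events(fused, truth, cfg.duration_s))
print(rep.sensitivity, rep.fd_per_24h)

hr = smooth_hr(ws.heart_rate(
    ws.detect_rpeaks_ensemble(rec.ecg.samples, rec.ecg.fs)))
for ev, st in zip(truth, ws.classify_tachy_response(hr, truth)):
    print(f"[{ev.start_s:.0f}, {ev.end_s:.0f}): {st.value} "
          f"(+{st.hr_increase_bpm:.1f} BPM)")
```

Output:

```
ground truth:  [(285.4, 325.4), (612.5, 652.5)]
eeg alarms:    [(283.0, 327.0), (610.0, 654.0)]
ecg alarms:    [(240.0, 380.0), (570.0, 710.0)]
fused alarms:  [(283.0, 327.0, 'eeg'), (610.0, 654.0, 'eeg')]
sensitivity=1.00  fd_per_24h=0.0  ppv=1.00  f1=1.00
seizure [285, 325): responder (+25.2 BPM)
seizure [612, 652): responder (+24.0 BPM)
```

Both seizures are found by both modalities; fusion keeps the tighter EEG
extents (the ECG events are minute-scale by construction), no false
alarms survive post-processing, and the configured 25 BPM ictal
heart-rate rise is recovered from the raw ECG, classifying the synthetic
patient as a tachycardia responder.

The same pipeline is available from the shell:

```sh
wearseiz simulate --seed 7 --out rec/          # EDF + ground-truth CSV
wearseiz detect-eeg --edf rec/recording.edf --model eeg.joblib --out eeg.csv
wearseiz detect-ecg --edf rec/recording.edf --model ecg.joblib --out ecg.csv
wearseiz fuse  --eeg eeg.csv --ecg ecg.csv --out fused.csv
wearseiz score --alarms fused.csv --truth rec/ground_truth.csv \
               --duration-s 1200 --out report.json
wearseiz review-export --edf rec/recording.edf --alarms fused.csv \
               --truth rec/ground_truth.csv --out pkg/
```

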