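"""ECG branch: R-peaks, heart rate, HR features, events, tachy response."""

import numpy as np
import pytest

from wearseiz.ecg import (ECGSeizureDetector, HeartRateSeries, RPeakSet,
                          classify_tachy_response, detect_rpeaks,
                          detect_rpeaks_ensemble, ensemble_rpeaks,
                          extend_annotations, extract_hr_features,
                          form_ecg_events, heart_rate, hr_grid, smooth_hr)
from wearseiz.events import AnnotationEvent
from wearseiz.synthetic import SimulationConfig, gen_ecg, gen_hr_profile

FS = 250.0


def _impulse_ecg(n_beats=30, rr_s=1.0):
    n = int((n_beats + 1) * rr_s * FS)
    x = 0.001 * np.random.default_rng(0).standard_normal(n)
    times = (np.arange(1, n_beats + 1) * rr_s)
    for t in times:
        i = int(t * FS)
        x[i - 3:i + 4] += np.hanning(7)  # narrow spike
    return x, times


# ---- R-peak detection ----------------------------------------------------

@pytest.mark.parametrize("detector", ["pan_tompkins", "local_max"])
def test_impulse_train_recovered_at_one_second_spacing(detector):
    x, times = _impulse_ecg()
    peaks = detect_rpeaks(x, FS, detector)
    assert len(peaks) == len(times)
    assert np.abs(peaks.peak_times_s - times).max() <= 1.5 / FS


def test_flat_signal_warns_and_returns_empty():
    with pytest.warns(UserWarning, match="flat"):
        peaks = detect_rpeaks(np.zeros(int(20 * FS)), FS)
    assert len(peaks) == 0


def test_rpeak_f1_on_synthetic_ecg_with_known_truth():
    cfg = SimulationConfig(duration_s=300.0, seizure_intervals=((120.0, 160.0),),
                           seed=5)
    sig, truth = gen_ecg(gen_hr_profile(cfg), FS, cfg.seed)
    det = detect_rpeaks_ensemble(sig, FS)
    d = det.peak_times_s
    tp = sum(1 for p in truth if np.abs(d - p).min() <= 0.05)
    f1 = 2 * tp / (len(d) + len(truth))
    assert f1 >= 0.99


# ---- ensemble ------------------------------------------------------------

def test_identical_sets_pass_through():
    t = np.array([1.0, 2.0, 3.0])
    out = ensemble_rpeaks([RPeakSet(t, "a"), RPeakSet(t, "b")])
    np.testing.assert_allclose(out.peak_times_s, t)


def test_majority_rule_keeps_two_of_three_drops_one_of_three():
    a = RPeakSet(np.array([1.0, 2.0, 3.0]), "a")
    b = RPeakSet(np.array([1.01, 2.01]), "b")        # misses beat 3
    c = RPeakSet(np.array([5.0]), "c")               # lone spurious peak
    out = ensemble_rpeaks([a, b, c])
    assert len(out) == 2
    assert np.abs(out.peak_times_s - [1.005, 2.005]).max() < 1e-6
    assert not np.any(np.isclose(out.peak_times_s, 5.0))


def test_jittered_detectors_average_toward_truth():
    rng = np.random.default_rng(3)
    truth = np.arange(1.0, 30.0, 0.8)
    sets = [RPeakSet(truth + rng.uniform(-0.03, 0.03, len(truth)), f"d{k}")
            for k in range(3)]
    out = ensemble_rpeaks(sets)
    assert len(out) == len(truth)
    assert np.abs(out.peak_times_s - truth).max() <= 0.03


def test_single_detector_passthrough_warns():
    with pytest.warns(UserWarning, match="passthrough"):
        out = ensemble_rpeaks([RPeakSet(np.array([1.0, 2.0]), "a")])
    assert len(out) == 2


# ---- heart rate ----------------------------------------------------------

@pytest.mark.parametrize("rr,expected", [(1.0, 60.0), (0.5, 120.0)])
def test_constant_rr_gives_constant_bpm(rr, expected):
    peaks = RPeakSet(np.arange(0, 30, rr), "t")
    hr = heart_rate(peaks)
    np.testing.assert_allclose(hr.bpm, expected)


def test_fewer_than_two_peaks_gives_empty_series():
    assert len(heart_rate(RPeakSet(np.array([5.0]), "t"))) == 0


def test_implausible_beats_are_rejected():
    t = np.concatenate([np.arange(0, 10, 1.0), [10.05], np.arange(11, 20, 1.0)])
    hr = heart_rate(RPeakSet(np.sort(t), "t"))
    assert hr.bpm.max() < 130  # the 0.05 s RR (1200 BPM) must not survive


def test_hr_ramp_recovered_within_2bpm():
    cfg = SimulationConfig(duration_s=400.0, baseline_hr=70.0,
                           ictal_hr_increase=25.0,
                           seizure_intervals=((150.0, 200.0),), seed=9)
    profile = gen_hr_profile(cfg)
    sig, _ = gen_ecg(profile, FS, cfg.seed)
    hr = smooth_hr(heart_rate(detect_rpeaks_ensemble(sig, FS)))
    truth = np.interp(hr.times_s, profile.times_s, profile.bpm)
    assert np.abs(hr.bpm - truth).max() < 2.0


# ---- annotation extension ------------------------------------------------

def test_extension_by_30s_each_side():
    ev = [AnnotationEvent(100.0, 160.0)]
    out = extend_annotations(ev, duration_s=1000.0)
    assert (out[0].start_s, out[0].end_s) == (70.0, 190.0)


def test_extension_clamps_at_recording_edges():
    out = extend_annotations([AnnotationEvent(10.0, 20.0)], duration_s=1000.0)
    assert (out[0].start_s, out[0].end_s) == (0.0, 50.0)


def test_extension_merges_events_brought_into_contact():
    out = extend_annotations([AnnotationEvent(100.0, 160.0),
                              AnnotationEvent(200.0, 260.0)],
                             duration_s=1000.0)
    assert [(e.start_s, e.end_s) for e in out] == [(70.0, 290.0)]


def test_double_extension_equals_single_wider_extension():
    evs = [AnnotationEvent(100.0, 160.0), AnnotationEvent(300.0, 320.0)]
    twice = extend_annotations(extend_annotations(evs, 30, 30, 1000.0),
                               30, 30, 1000.0)
    once = extend_annotations(evs, 60, 60, 1000.0)
    assert [(e.start_s, e.end_s) for e in twice] == \
        [(e.start_s, e.end_s) for e in once]


# ---- HR features ---------------------------------------------------------

def test_constant_hr_features():
    peaks = RPeakSet(np.arange(0.0, 120.0, 1.0), "t")
    hr = heart_rate(peaks)
    grid = hr_grid(120.0)
    X, valid = extract_hr_features(hr, grid)
    assert valid.all()
    names = ("mean_hr", "hr_range", "hr_slope", "rr_sd", "rmssd", "pnn50",
             "baseline_ratio")
    f = dict(zip(names, X[2]))
    assert f["mean_hr"] == pytest.approx(60.0)
    assert f["hr_slope"] == pytest.approx(0.0, abs=1e-9)
    assert f["rmssd"] == pytest.approx(0.0, abs=1e-12)
    assert f["baseline_ratio"] == pytest.approx(1.0)


def test_linear_ramp_slope():
    t = np.arange(0.0, 60.0, 1.0)
    hr = HeartRateSeries(t, 60.0 + 0.5 * t)  # 60 -> 90 BPM over one window
    grid = hr_grid(60.0)
    X, valid = extract_hr_features(hr, grid)
    assert valid[0]
    assert X[0, 2] == pytest.approx(0.5, abs=1e-9)


def test_hr_features_match_bruteforce_oracle():
    rng = np.random.default_rng(11)
    t = np.sort(rng.uniform(0, 300, 350))
    t = t[np.diff(t, prepend=-1) > 1e-3]
    bpm = 70 + 5 * rng.standard_normal(len(t))
    hr = HeartRateSeries(t, bpm)
    grid = hr_grid(300.0)
    X, valid = extract_hr_features(hr, grid, baseline_s=300.0)
    for i in range(grid.n_windows):
        w0, w1 = grid.window_interval(i)
        m = (t >= w0) & (t < w1)
        if m.sum() < 5:
            assert not valid[i]
            continue
        hw, tw = bpm[m], t[m]
        rr = 60.0 / hw
        assert X[i, 0] == pytest.approx(hw.mean())
        assert X[i, 1] == pytest.approx(hw.max() - hw.min())
        assert X[i, 2] == pytest.approx(np.polyfit(tw - w0, hw, 1)[0])
        assert X[i, 3] == pytest.approx(rr.std())
        assert X[i, 4] == pytest.approx(np.sqrt(np.mean(np.diff(rr) ** 2)))
        assert X[i, 5] == pytest.approx(np.mean(np.abs(np.diff(rr)) > 0.05))


def test_sparse_window_flagged_invalid():
    hr = HeartRateSeries(np.array([1.0, 2.0, 70.0]), np.array([60.0] * 3))
    X, valid = extract_hr_features(hr, hr_grid(80.0))
    assert not valid.any()
    assert np.isnan(X[~valid]).all()


# ---- event formation -----------------------------------------------------

def test_single_positive_window_gives_60s_event():
    grid = hr_grid(300.0)
    labels = np.zeros(grid.n_windows, dtype=int)
    labels[10] = 1  # starts at 100 s
    events = form_ecg_events(labels, grid)
    assert [(e.start_s, e.end_s) for e in events] == [(100.0, 160.0)]
    assert events[0].modality == "ecg"


def test_overlapping_positive_windows_merge():
    grid = hr_grid(300.0)
    labels = np.zeros(grid.n_windows, dtype=int)
    labels[[10, 11]] = 1  # 100 and 110 s
    events = form_ecg_events(labels, grid)
    assert [(e.start_s, e.end_s) for e in events] == [(100.0, 170.0)]


def test_no_positive_windows_no_events():
    grid = hr_grid(300.0)
    assert form_ecg_events(np.zeros(grid.n_windows, dtype=int), grid) == []


def test_event_durations_at_least_60_and_multiple_of_10():
    rng = np.random.default_rng(4)
    grid = hr_grid(600.0)
    labels = (rng.random(grid.n_windows) < 0.2).astype(int)
    for ev in form_ecg_events(labels, grid):
        assert ev.duration_s >= 60.0
        assert ev.duration_s % 10.0 == pytest.approx(0.0, abs=1e-9)


# ---- tachycardia response ------------------------------------------------

@pytest.mark.parametrize("peak,expected", [
    (95.0, "responder"), (80.0, "intermediate"), (70.0, "nonresponder")])
def test_tachy_threshold_arithmetic(peak, expected):
    t = np.arange(0.0, 300.0, 1.0)
    bpm = np.full_like(t, 70.0)
    bpm[(t >= 100) & (t < 140)] = peak
    hr = HeartRateSeries(t, bpm)
    [status] = classify_tachy_response(hr, [AnnotationEvent(100.0, 140.0)])
    assert status.value == expected


def test_missing_preictal_coverage_is_undetermined():
    hr = HeartRateSeries(np.arange(100.0, 200.0), np.full(100, 70.0))
    [status] = classify_tachy_response(hr, [AnnotationEvent(100.0, 140.0)])
    assert status.value == "undetermined"


# ---- detector ------------------------------------------------------------

def test_ecg_detector_single_class_raises():
    with pytest.raises(ValueError):
        ECGSeizureDetector().fit(np.zeros((5, 7)), np.zeros(5))


def test_ecg_detector_end_to_end_responders_vs_nonresponder():
    from wearseiz.evaluation import match_events
    from wearseiz.synthetic import make_cohort, default_config, gen_recording

    cohort = make_cohort(4, base_seed=0, duration_s=900.0, tachy="responder")
    det = ECGSeizureDetector()
    det.fit_recordings([m.recording for m in cohort],
                       [m.ground_truth for m in cohort])
    detected = total = 0
    for m in cohort:
        events = det.detect(m.recording)
        assert all(ev.duration_s >= 60.0 for ev in events)
        res = match_events(events, m.ground_truth, m.config.duration_s)
        detected += res.detected_seizures
        total += res.detected_seizures + res.missed_seizures
    assert detected / total >= 0.8  # training-set event sensitivity

    # a recording without any ictal HR change yields (almost) no positives
    cfg = default_config(99, duration_s=900.0, tachy="nonresponder")
    rec, _ = gen_recording(cfg)
    grid, X, valid, _ = det._features_for(rec)
    positives = int((det.decision_function(X[valid]) > 0).sum())
    assert positives <= max(1, int(0.01 * valid.sum()))


def test_ecg_model_persistence(tmp_path):
    rng = np.random.default_rng(2)
    X = rng.normal(size=(80, 7))
    y = (X[:, 0] > 0).astype(int)
    det = ECGSeizureDetector().fit(X, y)
    det.save(tmp_path / "m.joblib")
    back = ECGSeizureDetector.load(tmp_path / "m.joblib")
    np.testing.assert_array_equal(det.predict(X), back.predict(X))
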