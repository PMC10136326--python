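"""Single-lead ECG seizure detector and ictal-tachycardia analysis.

The detector never looks at ECG morphology beyond the R-peaks: an
ensemble of R-peak detectors yields beat times, instantaneous heart rate
is 60/RR after artifact rejection, and heart-rate features on 60 s
windows (10 s hop) feed a standardized classifier.  Because autonomic
seizure signatures lag and outlast the EEG pattern, training labels are
the ground-truth seizures extended by 30 s on both sides, and every
positive window contributes its full 60 s span to the alarm, so ECG
alarms are at least 60 s long.

A patient is a tachycardia *responder* when the peri-ictal heart-rate
increase over the pre-ictal baseline reaches 20 BPM, *intermediate* for
a positive increase below 20 BPM, and a *non-responder* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import joblib
import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .events import AnnotationEvent, DetectionEvent, merge_intervals
from .io import ROLE_ECG, Recording
from .segmentation import WindowGrid, make_grid

RPEAK_DETECTORS = ("pan_tompkins", "local_max")

#: plausible RR interval range (s) and max beat-to-beat fractional change
RR_MIN_S, RR_MAX_S, RR_MAX_JUMP = 0.24, 3.0, 0.35

HR_FEATURE_NAMES = ("mean_hr", "hr_range", "hr_slope", "rr_sd", "rmssd",
                    "pnn50", "baseline_ratio")

TACHY_THRESHOLD_BPM = 20.0


@dataclass(frozen=True)
class RPeakSet:
    peak_times_s: np.ndarray
    detector_id: str

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times_s, dtype=float)
        object.__setattr__(self, "peak_times_s", t)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times_s)


@dataclass(frozen=True)
class HeartRateSeries:
    """Time-stamped instantaneous heart rate in BPM."""

    times_s: np.ndarray
    bpm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        b = np.asarray(self.bpm, dtype=float)
        if len(t) != len(b):
            raise ValueError("times_s and bpm must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "bpm", b)

    def __len__(self) -> int:
        return len(self.times_s)

    def slice(self, start_s: float, end_s: float) -> "HeartRateSeries":
        m = (self.times_s >= start_s) & (self.times_s < end_s)
        return HeartRateSeries(self.times_s[m], self.bpm[m])


@dataclass(frozen=True)
class TachyStatus:
    value: str  # responder | intermediate | nonresponder | undetermined
    hr_increase_bpm: float


def _refine_to_local_max(x: np.ndarray, idx: np.ndarray, fs: float,
                         half_s: float = 0.05) -> np.ndarray:
    half = max(1, int(round(half_s * fs)))
    out = []
    for i in idx:
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out.append(lo + int(np.argmax(x[lo:hi])))
    return np.unique(out)


def detect_rpeaks(ecg: np.ndarray, fs: float,
                  detector_id: str = "pan_tompkins") -> RPeakSet:
    """Detect R-peaks with one member of the ensemble.

    ``pan_tompkins`` follows the classic derivative-square-integrate
    scheme with an adaptive threshold; ``local_max`` picks prominent
    local maxima of the band-passed signal against a rolling amplitude
    estimate.  A flat signal returns an empty set with a warning.
    """
    x = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ValueError(f"fs={fs} Hz too low for R-peak detection (need >= 100)")
    if len(x) < 10 * fs:
        raise ValueError("need at least 10 s of ECG")
    if np.std(x) < 1e-8:
        warnings.warn("flat ECG signal; no R-peaks detected")
        return RPeakSet(np.array([]), detector_id)
    if detector_id not in RPEAK_DETECTORS:
        raise ValueError(f"unknown detector {detector_id!r}")

    sos = sps.butter(2, [5.0, 20.0], btype="bandpass", fs=fs, output="sos")
    xf = sps.sosfiltfilt(sos, x)
    refractory = int(round(0.2 * fs))

    if detector_id == "pan_tompkins":
        deriv = np.gradient(xf)
        sq = deriv ** 2
        win = max(1, int(round(0.15 * fs)))
        integ = np.convolve(sq, np.ones(win) / win, mode="same")
        thr = 0.3 * np.quantile(integ, 0.99)
        idx, _ = sps.find_peaks(integ, height=thr, distance=refractory)
    else:  # local_max
        env = np.abs(xf)
        thr = 0.4 * np.quantile(env, 0.99)
        idx, _ = sps.find_peaks(env, height=thr, distance=refractory)

    idx = _refine_to_local_max(xf, idx, fs)
    return RPeakSet(idx / fs, detector_id)


def ensemble_rpeaks(peak_sets: list[RPeakSet], tol_s: float = 0.1) -> RPeakSet:
    """Majority-vote fusion of several R-peak detectors.

    Peaks from all detectors are greedily clustered within ``tol_s``
    (at most one peak per detector per cluster); clusters supported by a
    strict majority of detectors survive as their centroid."""
    if len(peak_sets) == 1:
        warnings.warn("single R-peak detector: ensemble is a passthrough")
        return replace(peak_sets[0], detector_id="ensemble")
    if not peak_sets:
        raise ValueError("need at least one peak set")
    n_det = len(peak_sets)
    pooled = sorted(
        (t, d) for d, ps in enumerate(peak_sets) for t in ps.peak_times_s
    )
    centroids = []
    i = 0
    while i < len(pooled):
        members = [pooled[i]]
        j = i + 1
        while j < len(pooled):
            t, d = pooled[j]
            ctr = np.mean([m[0] for m in members])
            if t - ctr <= tol_s and d not in {m[1] for m in members}:
                members.append(pooled[j])
                j += 1
            elif t - ctr <= tol_s:
                break  # same detector fired twice within tol: new cluster
            else:
                break
        if len(members) > n_det / 2:
            centroids.append(float(np.mean([m[0] for m in members])))
        i = j if j > i else i + 1
    t = np.array(centroids)
    keep = np.ones(len(t), dtype=bool)
    keep[1:] = np.diff(t) > 1e-6
    return RPeakSet(t[keep], "ensemble")


def detect_rpeaks_ensemble(ecg: np.ndarray, fs: float,
                           tol_s: float = 0.1) -> RPeakSet:
    """Run every detector in the ensemble and fuse by majority vote."""
    sets = [detect_rpeaks(ecg, fs, d) for d in RPEAK_DETECTORS]
    if any(len(s) == 0 for s in sets):
        return RPeakSet(np.array([]), "ensemble")
    return ensemble_rpeaks(sets, tol_s)


def clean_rr(peaks: RPeakSet) -> tuple[np.ndarray, np.ndarray]:
    """(beat midpoint times, RR intervals) after artifact rejection:
    RR outside [0.24, 3] s or a beat-to-beat change above 35% is dropped."""
    t = peaks.peak_times_s
    if len(t) < 2:
        return np.array([]), np.array([])
    rr = np.diff(t)
    mid = (t[:-1] + t[1:]) / 2
    ok = (rr >= RR_MIN_S) & (rr <= RR_MAX_S)
    prev = np.concatenate([[rr[0]], rr[:-1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        jump = np.abs(rr - prev) / prev
    ok &= jump <= RR_MAX_JUMP
    return mid[ok], rr[ok]


def heart_rate(peaks: RPeakSet) -> HeartRateSeries:
    """Instantaneous heart rate (60/RR, BPM) at beat midpoints after
    RR-artifact rejection.  Fewer than 2 peaks yields an empty series."""
    mid, rr = clean_rr(peaks)
    if len(mid) == 0:
        return HeartRateSeries(np.array([]), np.array([]))
    return HeartRateSeries(mid, 60.0 / rr)


def smooth_hr(hr: HeartRateSeries, win_beats: int = 7) -> HeartRateSeries:
    """Symmetric moving-average smoothing over ``win_beats`` beats.

    A centred mean suppresses independent beat-timing jitter by ~sqrt(n)
    and is unbiased on linear heart-rate ramps; gross RR artifacts are
    already rejected upstream (:func:`clean_rr`), so robustness to
    outliers is not needed here."""
    if len(hr) == 0 or win_beats <= 1:
        return hr
    k = win_beats if win_beats % 2 == 1 else win_beats + 1
    pad = k // 2
    padded = np.concatenate([np.repeat(hr.bpm[0], pad), hr.bpm,
                             np.repeat(hr.bpm[-1], pad)])
    sm = np.convolve(padded, np.ones(k) / k, mode="valid")
    return HeartRateSeries(hr.times_s, sm)


def extend_annotations(events: list[AnnotationEvent], pre_s: float = 30.0,
                       post_s: float = 30.0,
                       duration_s: float | None = None) -> list[AnnotationEvent]:
    """Extend each event by ``pre_s``/``post_s``, clamp to the recording,
    and merge any overlaps.  Extending twice with 30 s equals extending
    once with 60 s only up to the merging step, which is applied here."""
    if not events:
        return []
    spans = []
    for ev in events:
        s = max(0.0, ev.start_s - pre_s)
        e = ev.end_s + post_s if duration_s is None else min(duration_s,
                                                             ev.end_s + post_s)
        spans.append((s, e))
    ref = events[0]
    return [AnnotationEvent(s, e, ref.label, ref.source)
            for s, e in merge_intervals(spans)]


def hr_grid(duration_s: float, win_s: float = 60.0,
            hop_s: float = 10.0) -> WindowGrid:
    """The ECG window grid for a recording of ``duration_s`` seconds."""
    return make_grid(int(np.floor(duration_s)), 1.0, win_s, hop_s)


def extract_hr_features(hr: HeartRateSeries, grid: WindowGrid,
                        baseline_s: float = 300.0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window heart-rate features on the 60 s / 10 s grid.

    Returns ``(X, valid)`` where ``X`` is (n_windows, 7) and ``valid``
    flags windows with at least 5 beats; invalid windows hold NaN and are
    excluded from classification.  ``baseline_ratio`` compares the window
    mean to the mean over the trailing ``baseline_s`` (5 min) of history,
    falling back to all available history, then to 1.
    """
    n = grid.n_windows
    X = np.full((n, len(HR_FEATURE_NAMES)), np.nan)
    valid = np.zeros(n, dtype=bool)
    t, bpm = hr.times_s, hr.bpm
    for i in range(n):
        w0, w1 = grid.window_interval(i)
        m = (t >= w0) & (t < w1)
        if m.sum() < 5:
            continue
        valid[i] = True
        tw, hw = t[m], bpm[m]
        rr = 60.0 / hw
        mean_hr = hw.mean()
        hr_range = hw.max() - hw.min()
        slope = np.polyfit(tw - w0, hw, 1)[0] if len(tw) > 1 else 0.0
        rr_sd = rr.std()
        drr = np.diff(rr)
        rmssd = np.sqrt((drr ** 2).mean()) if len(drr) else 0.0
        pnn50 = float((np.abs(drr) > 0.05).mean()) if len(drr) else 0.0
        hist = (t >= w0 - baseline_s) & (t < w0)
        if not hist.any():
            hist = t < w0
        base = bpm[hist].mean() if hist.any() else mean_hr
        X[i] = (mean_hr, hr_range, slope, rr_sd, rmssd, pnn50,
                mean_hr / base if base > 0 else 1.0)
    return X, valid


def form_ecg_events(window_labels: np.ndarray, grid: WindowGrid,
                    scores: np.ndarray | None = None) -> list[DetectionEvent]:
    """Each positive window contributes its full [s, s+60) span;
    overlapping/contiguous spans merge, so events last >= 60 s."""
    labels = np.asarray(window_labels, dtype=int)
    spans = [grid.window_interval(i) for i in np.flatnonzero(labels)]
    events = []
    for s, e in merge_intervals(spans):
        score = 0.0
        if scores is not None:
            idx = [i for i in np.flatnonzero(labels)
                   if s <= i * grid.hop_s < e]
            if idx:
                score = float(np.mean(np.asarray(scores)[idx]))
        events.append(DetectionEvent(start_s=s, end_s=e, modality="ecg",
                                     score=score))
    return events


#: peri-ictal increases within this band are indistinguishable from
#: hour-scale baseline wander (bounded by ~6 BPM at a 2 BPM wander SD)
#: and therefore do not count as a heart-rate response
DEFAULT_TACHY_TOLERANCE_BPM = 6.0


def classify_tachy_response(hr: HeartRateSeries,
                            seizure_events: list[AnnotationEvent],
                            baseline_win_s: float = 60.0,
                            post_s: float = 30.0,
                            tolerance_bpm: float = DEFAULT_TACHY_TOLERANCE_BPM
                            ) -> list[TachyStatus]:
    """Per-seizure tachycardia response.

    increase = max HR in [start, end+30 s] - median HR in the
    ``baseline_win_s`` pre-ictal window; >= 20 BPM -> responder,
    above ``tolerance_bpm`` but below 20 -> intermediate, otherwise
    nonresponder.  The peri-ictal maximum of a wandering baseline sits
    above its pre-ictal median even without any ictal effect, so
    increases inside the wander band must not count as a response;
    ``tolerance_bpm=0`` recovers the strict zero threshold.  Missing
    pre-ictal coverage yields an ``undetermined`` status.
    """
    out = []
    for ev in seizure_events:
        base = hr.slice(ev.start_s - baseline_win_s, ev.start_s)
        m = (hr.times_s >= ev.start_s) & (hr.times_s <= ev.end_s + post_s)
        if len(base) == 0 or not m.any():
            out.append(TachyStatus("undetermined", float("nan")))
            continue
        inc = float(hr.bpm[m].max() - np.median(base.bpm))
        if inc >= TACHY_THRESHOLD_BPM:
            value = "responder"
        elif inc > tolerance_bpm:
            value = "intermediate"
        else:
            value = "nonresponder"
        out.append(TachyStatus(value, inc))
    return out


class ECGSeizureDetector(ClassifierMixin, BaseEstimator):
    """Standardized classifier over 60 s heart-rate feature windows.

    Mirrors :class:`wearseiz.eeg.EEGSeizureDetector`: ``fit`` /
    ``predict`` / ``decision_function`` act on window feature matrices;
    :meth:`fit_recordings` derives features and (30 s-extended) labels
    from Recordings, and :meth:`detect` emits >= 60 s alarm events.
    The window classifier defaults to the same RBF-SVM family as the EEG
    branch (``classifier="svm-rbf"``; ``"svm-linear"`` available).
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "auto",
                 classifier: str = "svm-rbf",
                 class_weight: str | dict | None = "balanced",
                 win_s: float = 60.0, hop_s: float = 10.0,
                 extend_s: float = 30.0, decision_threshold: float = 0.0,
                 baseline_s: float = 300.0, random_state: int = 0):
        self.C = C
        self.gamma = gamma
        self.classifier = classifier
        self.class_weight = class_weight
        self.win_s = win_s
        self.hop_s = hop_s
        self.extend_s = extend_s
        self.decision_threshold = decision_threshold
        self.baseline_s = baseline_s
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training needs both classes of HR windows")
        if self.classifier == "svm-rbf":
            clf = SVC(kernel="rbf", C=self.C, gamma=self.gamma,
                      class_weight=self.class_weight,
                      random_state=self.random_state)
        elif self.classifier == "svm-linear":
            clf = SVC(kernel="linear", C=self.C,
                      class_weight=self.class_weight,
                      random_state=self.random_state)
        else:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        self.pipeline_ = Pipeline([("scale", StandardScaler()), ("clf", clf)])
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.named_steps["clf"].classes_
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        self._check_fitted()
        return self.pipeline_.decision_function(np.asarray(X, dtype=float))

    def predict(self, X):
        return (self.decision_function(X) > self.decision_threshold).astype(int)

    def _check_fitted(self) -> None:
        if not hasattr(self, "pipeline_"):
            raise ValueError("detector is not fitted")

    # -- recording-level surface ---------------------------------------
    def _features_for(self, recording: Recording):
        ecg_ch = recording.get(ROLE_ECG)
        peaks = detect_rpeaks_ensemble(ecg_ch.samples, ecg_ch.fs)
        hr = heart_rate(peaks)
        grid = hr_grid(recording.duration_s, self.win_s, self.hop_s)
        X, valid = extract_hr_features(hr, grid, self.baseline_s)
        return grid, X, valid, hr

    def fit_recordings(self, recordings, annotations):
        from .segmentation import label_windows
        Xs, ys = [], []
        for rec, events in zip(recordings, annotations):
            grid, X, valid, _ = self._features_for(rec)
            ext = extend_annotations(
                [ev for ev in events if ev.label == "seizure"],
                self.extend_s, self.extend_s, rec.duration_s)
            y = label_windows(grid, ext)
            Xs.append(X[valid])
            ys.append(y[valid])
        return self.fit(np.vstack(Xs), np.concatenate(ys))

    def detect(self, recording: Recording) -> list[DetectionEvent]:
        self._check_fitted()
        grid, X, valid, _ = self._features_for(recording)
        labels = np.zeros(grid.n_windows, dtype=int)
        scores = np.zeros(grid.n_windows)
        if valid.any():
            sc = self.decision_function(X[valid])
            scores[valid] = sc
            labels[valid] = (sc > self.decision_threshold).astype(int)
        return form_ecg_events(labels, grid, scores=scores)

    def save(self, path) -> str:
        self._check_fitted()
        joblib.dump({"format": "wearseiz-ecg-model-v1", "estimator": self}, path)
        return str(path)

    @classmethod
    def load(cls, path) -> "ECGSeizureDetector":
        blob = joblib.load(path)
        if blob.get("format") != "wearseiz-ecg-model-v1":
            raise ValueError(f"{path}: not a wearseiz ECG model file")
        return blob["estimator"]


def train_ecg_classifier(features, window_labels,
                         hyperparams: dict | None = None) -> ECGSeizureDetector:
    """Functional wrapper over :class:`ECGSeizureDetector.fit`."""
    det = ECGSeizureDetector(**(hyperparams or {}))
    return det.fit(features, window_labels)
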