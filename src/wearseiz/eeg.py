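"""Behind-the-ear EEG seizure detector.

Pipeline: 0.5-35 Hz zero-phase band-pass -> 2 s windows at 1 s hop ->
67-feature extraction (:mod:`wearseiz.eeg_features`) -> standardized
RBF-SVM window classifier -> temporal post-processing that keeps a
detection only when at least 8 of 10 consecutive windows are positive.
A qualifying group of ``group_len`` windows contributes the span
``[g*hop, (g+group_len)*hop)``; overlapping or contiguous spans are
merged, so the shortest possible alarm is ``group_len*hop`` = 10 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .eeg_features import extract_features
from .events import DetectionEvent, merge_intervals
from .io import ROLE_EEG_CROSS, ROLE_EEG_IPSI, Recording
from .segmentation import WindowGrid, label_windows, make_grid


def bandpass(x: np.ndarray, fs: float, low: float = 0.5,
             high: float = 35.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (default 0.5-35 Hz).

    Matches the display filtering used when alarms are reviewed; DC is
    rejected and power-line frequencies are strongly attenuated.
    """
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} Hz must exceed twice the {high} Hz band edge")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


@dataclass(frozen=True)
class PostprocessRule:
    """Keep a detection iff >= ``min_positives`` of ``group_len``
    consecutive windows are classifier-positive."""

    group_len: int = 10
    min_positives: int = 8

    def __post_init__(self) -> None:
        if not 1 <= self.min_positives <= self.group_len:
            raise ValueError("need 1 <= min_positives <= group_len")


def postprocess(window_labels: np.ndarray, grid: WindowGrid,
                rule: PostprocessRule = PostprocessRule(),
                scores: np.ndarray | None = None,
                modality: str = "eeg") -> list[DetectionEvent]:
    """Turn binary window labels into alarm events under the m-of-n rule.

    Sequences shorter than ``group_len`` yield no events.  The event score
    is the mean decision value of the windows inside the event span.
    """
    labels = np.asarray(window_labels, dtype=int)
    if labels.shape[0] != grid.n_windows:
        raise ValueError("labels not aligned to grid")
    n = len(labels)
    if n < rule.group_len:
        return []
    counts = np.convolve(labels, np.ones(rule.group_len, dtype=int),
                         mode="valid")
    qualifying = np.flatnonzero(counts >= rule.min_positives)
    spans = [(g * grid.hop_s, (g + rule.group_len) * grid.hop_s)
             for g in qualifying]
    events = []
    for s, e in merge_intervals(spans):
        score = 0.0
        if scores is not None:
            w0 = int(round(s / grid.hop_s))
            w1 = min(n, int(round(e / grid.hop_s)))
            score = float(np.mean(scores[w0:w1]))
        events.append(DetectionEvent(start_s=s, end_s=e,
                                     modality=modality, score=score))
    return events


class EEGSeizureDetector(ClassifierMixin, BaseEstimator):
    """RBF-SVM window classifier over the 67-feature bte-EEG bank.

    The sklearn surface (``fit``/``predict``/``decision_function``)
    operates on window feature matrices so the estimator composes with
    pipelines and model selection; :meth:`fit_recordings` and
    :meth:`detect` wrap the full signal-to-alarms chain.

    Parameters
    ----------
    C, gamma : RBF-SVM hyperparameters (defaults C=1, gamma=1/n_features).
    class_weight : passed to the SVM; seizure windows are rare, so the
        default inverse-frequency weighting ("balanced") is kept.
    win_s, hop_s : segmentation grid (2 s / 1 s).
    band : band-pass edges in Hz applied before feature extraction.
    group_len, min_positives : post-processing rule (8-of-10).
    decision_threshold : decision-function threshold for a positive
        window (0 = the SVM margin).
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "auto",
                 class_weight: str | dict | None = "balanced",
                 win_s: float = 2.0, hop_s: float = 1.0,
                 band: tuple[float, float] = (0.5, 35.0),
                 group_len: int = 10, min_positives: int = 8,
                 decision_threshold: float = 0.0,
                 entropy_decimate: int = 2, random_state: int = 0):
        self.C = C
        self.gamma = gamma
        self.class_weight = class_weight
        self.win_s = win_s
        self.hop_s = hop_s
        self.band = band
        self.group_len = group_len
        self.min_positives = min_positives
        self.decision_threshold = decision_threshold
        self.entropy_decimate = entropy_decimate
        self.random_state = random_state

    # -- sklearn window-level surface ----------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_windows, n_features)")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError(
                "training needs both seizure and non-seizure windows; "
                f"got single class {classes!r}"
            )
        self.pipeline_ = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=self.C, gamma=self.gamma,
                        class_weight=self.class_weight,
                        random_state=self.random_state)),
        ])
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.named_steps["svm"].classes_
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
    @property
    def rule(self) -> PostprocessRule:
        return PostprocessRule(self.group_len, self.min_positives)

    def _grid_and_features(self, recording: Recording):
        cross = recording.get(ROLE_EEG_CROSS)
        ipsi = recording.get(ROLE_EEG_IPSI)
        if cross.fs != ipsi.fs:
            raise ValueError("EEG channels must share a sampling rate")
        fs = cross.fs
        xc = bandpass(cross.samples, fs, *self.band)
        xi = bandpass(ipsi.samples, fs, *self.band)
        grid = make_grid(len(xc), fs, self.win_s, self.hop_s)
        X = extract_features(xc, xi, fs, grid,
                             entropy_decimate=self.entropy_decimate)
        return grid, X

    def fit_recordings(self, recordings, annotations):
        """Fit from Recordings plus their ground-truth annotation lists.

        Windows are labelled positive when at least half the window
        overlaps a ground-truth seizure."""
        Xs, ys = [], []
        for rec, events in zip(recordings, annotations):
            grid, X = self._grid_and_features(rec)
            Xs.append(X)
            ys.append(label_windows(grid, list(events)))
        return self.fit(np.vstack(Xs), np.concatenate(ys))

    def detect(self, recording: Recording) -> list[DetectionEvent]:
        """Run the full chain on one recording and return alarm events."""
        self._check_fitted()
        grid, X = self._grid_and_features(recording)
        scores = self.decision_function(X)
        labels = (scores > self.decision_threshold).astype(int)
        return postprocess(labels, grid, self.rule, scores=scores,
                           modality="eeg")

    # -- persistence ----------------------------------------------------
    def save(self, path) -> str:
        self._check_fitted()
        joblib.dump({"format": "wearseiz-eeg-model-v1", "estimator": self}, path)
        return str(path)

    @classmethod
    def load(cls, path) -> "EEGSeizureDetector":
        blob = joblib.load(path)
        if blob.get("format") != "wearseiz-eeg-model-v1":
            raise ValueError(f"{path}: not a wearseiz EEG model file")
        return blob["estimator"]


def train_eeg_classifier(features, window_labels,
                         hyperparams: dict | None = None) -> EEGSeizureDetector:
    """Functional wrapper over :class:`EEGSeizureDetector.fit`."""
    det = EEGSeizureDetector(**(hyperparams or {}))
    return det.fit(features, window_labels)
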