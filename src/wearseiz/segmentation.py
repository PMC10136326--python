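"""Sliding-window segmentation shared by the EEG and ECG detectors.

The EEG detector uses 2 s windows at a 1 s hop; the ECG detector uses
60 s windows at a 10 s hop.  Window ``i`` covers the half-open interval
``[i*hop_s, i*hop_s + win_s)`` and the last window must lie fully inside
the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import AnnotationEvent


class EmptyGridError(ValueError):
    """Signal shorter than a single window."""


@dataclass(frozen=True)
class WindowGrid:
    win_s: float
    hop_s: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.hop_s > self.win_s:
            raise ValueError("hop_s must not exceed win_s")
        if self.hop_s <= 0:
            raise ValueError("hop_s must be positive")

    @property
    def window_starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.hop_s

    def window_interval(self, i: int) -> tuple[float, float]:
        return i * self.hop_s, i * self.hop_s + self.win_s


def make_grid(n_samples: int, fs: float, win_s: float = 2.0,
              hop_s: float = 1.0) -> WindowGrid:
    """Build the window grid covering a signal of ``n_samples`` at ``fs``."""
    duration = n_samples / fs
    if duration + 1e-9 < win_s:
        raise EmptyGridError(
            f"signal of {duration:.3f}s is shorter than one {win_s}s window"
        )
    n = int(np.floor((duration - win_s) / hop_s + 1e-9)) + 1
    return WindowGrid(win_s=win_s, hop_s=hop_s, n_windows=n)


def window_view(signal: np.ndarray, fs: float, grid: WindowGrid) -> np.ndarray:
    """(n_windows, win_samples) strided view of the signal on the grid."""
    win = int(round(grid.win_s * fs))
    hop = int(round(grid.hop_s * fs))
    x = np.asarray(signal, dtype=float)
    idx = np.arange(grid.n_windows)[:, None] * hop + np.arange(win)[None, :]
    return x[idx]


def label_windows(grid: WindowGrid, events: list[AnnotationEvent],
                  min_overlap: float = 0.5) -> np.ndarray:
    """Binary window labels: 1 iff at least ``min_overlap`` of the window
    overlaps any seizure event.  Used to derive training targets from
    ground-truth annotations."""
    labels = np.zeros(grid.n_windows, dtype=int)
    seiz = [ev for ev in events if ev.label == "seizure"]
    for i in range(grid.n_windows):
        w0, w1 = grid.window_interval(i)
        ov = sum(max(0.0, min(w1, ev.end_s) - max(w0, ev.start_s))
                 for ev in seiz)
        if ov >= min_overlap * grid.win_s:
            labels[i] = 1
    return labels
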