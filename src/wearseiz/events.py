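"""Time-interval event types shared by every module.

All times are float seconds from recording start and every interval is
half-open, ``[start_s, end_s)``: two events *overlap* iff their
intersection is non-empty, so ``[a, b)`` and ``[b, c)`` touch but do not
overlap, and durations are additive under concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

ANNOTATION_LABELS = ("seizure", "artifact", "other", "alarm")
ANNOTATION_SOURCES = ("ground_truth", "algorithm", "reader")
MODALITIES = ("eeg", "ecg", "fused")

#: minimum alarm duration per modality, seconds
MIN_EVENT_DURATION_S = {"eeg": 10.0, "ecg": 60.0, "fused": 10.0}


@dataclass(frozen=True, order=True)
class AnnotationEvent:
    """A labelled time interval attached to a recording."""

    start_s: float
    end_s: float
    label: str = "seizure"
    source: str = "ground_truth"

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"end_s must exceed start_s, got [{self.start_s}, {self.end_s})"
            )
        if self.start_s < 0:
            raise ValueError(f"start_s must be >= 0, got {self.start_s}")
        if self.label not in ANNOTATION_LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {ANNOTATION_LABELS}"
            )
        if self.source not in ANNOTATION_SOURCES:
            raise ValueError(
                f"unknown source {self.source!r}; expected one of {ANNOTATION_SOURCES}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlaps(self, other: "AnnotationEvent | DetectionEvent") -> bool:
        return overlaps(self.start_s, self.end_s, other.start_s, other.end_s)


@dataclass(frozen=True, order=True)
class DetectionEvent:
    """An algorithm alarm interval with its source modality.

    ``score`` is the mean classifier decision value over the windows that
    contributed to the event (0.0 when unavailable, e.g. events read back
    from CSV).
    """

    start_s: float
    end_s: float
    modality: str = "eeg"
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"end_s must exceed start_s, got [{self.start_s}, {self.end_s})"
            )
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlaps(self, other: "AnnotationEvent | DetectionEvent") -> bool:
        return overlaps(self.start_s, self.end_s, other.start_s, other.end_s)


def overlaps(a0: float, a1: float, b0: float, b1: float) -> bool:
    """Non-empty intersection of half-open intervals [a0,a1) and [b0,b1)."""
    return a0 < b1 and b0 < a1


def merge_intervals(
    intervals: Iterable[tuple[float, float]], *, gap: float = 0.0
) -> list[tuple[float, float]]:
    """Union of half-open intervals, merging pairs that overlap or whose gap
    is <= ``gap``.  With the default ``gap=0`` contiguous intervals
    ([a,b) and [b,c)) are merged into one span (the union is connected)."""
    ivs = sorted(intervals)
    merged: list[list[float]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def check_disjoint(events: Sequence[AnnotationEvent | DetectionEvent]) -> None:
    """Raise ValueError if any two events in the sequence overlap."""
    ordered = sorted(events, key=lambda ev: ev.start_s)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start_s < prev.end_s:
            raise ValueError(
                f"overlapping events: [{prev.start_s}, {prev.end_s}) and "
                f"[{cur.start_s}, {cur.end_s})"
            )


def clip_event(ev: AnnotationEvent, duration_s: float) -> AnnotationEvent:
    """Clamp an event to [0, duration_s)."""
    return replace(
        ev, start_s=max(0.0, ev.start_s), end_s=min(duration_s, ev.end_s)
    )
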