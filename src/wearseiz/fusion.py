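"""Late decision-level 'OR' fusion of the two unimodal alarm streams.

An alarm is raised if either modality fires.  When an ECG alarm overlaps
one or more EEG alarms, the EEG segment(s) stand and the ECG alarm is
dropped whole: the EEG detector localizes the event in time far more
tightly (10 s resolution versus 60 s), so its extent is preferred.
Half-open interval semantics apply: [a, b) and [b, c) touch but do not
overlap, and both are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .events import DetectionEvent, check_disjoint, overlaps


@dataclass
class FusedAlarmSet:
    """Sorted, non-overlapping fused alarms with per-event provenance."""

    events: list[DetectionEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda ev: ev.start_s)
        check_disjoint(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def fuse_or(eeg_events: list[DetectionEvent],
            ecg_events: list[DetectionEvent],
            strategy: str = "or") -> FusedAlarmSet:
    """Fuse unimodal alarms with the 'OR' strategy.

    Every EEG event is kept unchanged; an ECG event is kept iff it
    overlaps no EEG event.  Inputs must each be internally
    non-overlapping.  The experimental ``strategy="and"`` keeps only EEG
    events that overlap at least one ECG event (off by default and not
    part of the standard framework).
    """
    check_disjoint(eeg_events)
    check_disjoint(ecg_events)
    if strategy == "or":
        kept = list(eeg_events)
        for ecg_ev in ecg_events:
            if not any(overlaps(ecg_ev.start_s, ecg_ev.end_s,
                                e.start_s, e.end_s) for e in eeg_events):
                kept.append(ecg_ev)
    elif strategy == "and":
        kept = [e for e in eeg_events
                if any(overlaps(e.start_s, e.end_s, c.start_s, c.end_s)
                       for c in ecg_events)]
    else:
        raise ValueError(f"unknown fusion strategy {strategy!r}")
    return FusedAlarmSet(kept)
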