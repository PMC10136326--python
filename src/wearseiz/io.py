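"""Recording container and file I/O (EDF signals, CSV annotation sidecars).

A :class:`Recording` holds the wearable montage this package targets: two
behind-the-ear EEG channels (one cross-head, one ipsilateral to the
seizure-onset hemisphere), one single-lead ECG channel, and optionally a
precomputed heart-rate channel.  EDF channel labels vary between
recorders, so labels are mapped to roles through a configurable
regex table rather than hard-coded names.

All modules downstream consume times as float seconds from recording
start with half-open intervals; files are read once, here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _edf
from .events import AnnotationEvent

ROLE_EEG_CROSS = "eeg_crosshead"
ROLE_EEG_IPSI = "eeg_ipsilateral"
ROLE_ECG = "ecg"
ROLE_HR = "heart_rate"
ROLES = (ROLE_EEG_CROSS, ROLE_EEG_IPSI, ROLE_ECG, ROLE_HR)

#: default label→role mapping; first matching pattern wins
DEFAULT_CHANNEL_MAP: tuple[tuple[str, str], ...] = (
    (r"(?i)cross", ROLE_EEG_CROSS),
    (r"(?i)ipsi", ROLE_EEG_IPSI),
    (r"(?i)\b(ecg|ekg)\b", ROLE_ECG),
    (r"(?i)(heart.?rate|\bhr\b)", ROLE_HR),
)

_ROLE_DIMS = {ROLE_EEG_CROSS: "uV", ROLE_EEG_IPSI: "uV", ROLE_ECG: "mV",
              ROLE_HR: "bpm"}


class ChannelMappingError(ValueError):
    """No channel label could be mapped to a known role."""


class FormatError(ValueError):
    """File is not readable as the expected format."""


@dataclass
class Channel:
    label: str
    role: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class Recording:
    """Multichannel physiological recording with per-channel roles."""

    patient_id: str
    channels: list[Channel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.channels:
            durs = [ch.duration_s for ch in self.channels]
            ref = durs[0]
            for ch, d in zip(self.channels, durs):
                if abs(d - ref) > 1.0 / ch.fs:
                    raise ValueError(
                        f"channel {ch.label!r} duration {d:.3f}s deviates from "
                        f"{ref:.3f}s by more than one sample"
                    )

    @property
    def duration_s(self) -> float:
        if not self.channels:
            return 0.0
        return max(ch.duration_s for ch in self.channels)

    def get(self, role: str) -> Channel:
        found = [ch for ch in self.channels if ch.role == role]
        if not found:
            raise KeyError(f"recording has no channel with role {role!r}")
        if len(found) > 1:
            raise KeyError(f"recording has {len(found)} channels with role {role!r}")
        return found[0]

    @property
    def eeg_channels(self) -> list[Channel]:
        return [ch for ch in self.channels
                if ch.role in (ROLE_EEG_CROSS, ROLE_EEG_IPSI)]

    @property
    def ecg(self) -> Channel:
        return self.get(ROLE_ECG)


def map_label(label: str,
              channel_map=DEFAULT_CHANNEL_MAP) -> str | None:
    for pattern, role in channel_map:
        if re.search(pattern, label):
            return role
    return None


def read_recording(path, channel_map=DEFAULT_CHANNEL_MAP) -> Recording:
    """Read an EDF file into a :class:`Recording` with mapped channel roles.

    Signals are returned in the physical units stored in the file (µV for
    EEG, mV for ECG by this package's writer).  Channels whose label maps
    to no role are dropped; if *none* maps, a :class:`ChannelMappingError`
    listing the unmapped labels is raised.
    """
    try:
        edf = _edf.read_edf(path)
    except ValueError as exc:
        raise FormatError(str(exc)) from None
    channels, unmapped = [], []
    for sig in edf.signals:
        role = map_label(sig.label, channel_map)
        if role is None:
            unmapped.append(sig.label)
            continue
        channels.append(Channel(label=sig.label, role=role,
                                samples=sig.samples, fs=sig.fs))
    if not channels:
        raise ChannelMappingError(
            f"no channel label matched a role; unmapped labels: {unmapped}"
        )
    return Recording(patient_id=edf.patient_id or "unknown", channels=channels)


def write_recording(recording: Recording, path,
                    physical_range: dict[str, float] | None = None) -> str:
    """Write a Recording to EDF.  ``physical_range`` optionally maps a role
    to a symmetric ±range; otherwise the range is fitted to the data."""
    if not recording.channels:
        raise ValueError("recording has no channels")
    signals = []
    for ch in recording.channels:
        if not np.all(np.isfinite(ch.samples)):
            raise ValueError(f"non-finite samples in channel {ch.label!r}")
        bound = (physical_range or {}).get(ch.role)
        signals.append(_edf.EdfSignal(
            label=ch.label, samples=ch.samples, fs=ch.fs,
            physical_dim=_ROLE_DIMS[ch.role],
            physical_min=-bound if bound else None,
            physical_max=bound if bound else None,
        ))
    return _edf.write_edf(path, _edf.EdfFile(
        signals=signals, patient_id=recording.patient_id))


def read_annotations(path) -> list[AnnotationEvent]:
    """Read a CSV annotation sidecar (header ``start_s,end_s,label,source``).

    Rows are validated (end > start, known label/source) and returned
    sorted by start time; a malformed row raises ValueError naming it.
    """
    df = pd.read_csv(path)
    required = ["start_s", "end_s", "label", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    events = []
    for idx, row in df.iterrows():
        try:
            events.append(AnnotationEvent(
                start_s=float(row["start_s"]), end_s=float(row["end_s"]),
                label=str(row["label"]), source=str(row["source"]),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx + 1}: {exc}") from None
    return sorted(events, key=lambda ev: (ev.start_s, ev.end_s))


def write_annotations(events, path) -> str:
    """Write annotation events to CSV; round trip through
    :func:`read_annotations` is lossless."""
    df = pd.DataFrame(
        [(ev.start_s, ev.end_s, ev.label, ev.source) for ev in events],
        columns=["start_s", "end_s", "label", "source"],
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return str(path)


def validate_recording(recording: Recording) -> list[str]:
    """Return a list of human-readable problems (empty = valid)."""
    problems = []
    roles = [ch.role for ch in recording.channels]
    if ROLE_EEG_CROSS not in roles and ROLE_EEG_IPSI not in roles:
        problems.append("no EEG channel (cross-head or ipsilateral) present")
    if roles.count(ROLE_ECG) > 1:
        problems.append("more than one ECG channel")
    for ch in recording.channels:
        if not np.all(np.isfinite(ch.samples)):
            problems.append(f"channel {ch.label!r} contains non-finite samples")
    return problems
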