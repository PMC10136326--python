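"""Semi-automated review workflow: package alarms for human readers and
ingest their relabels.

Readers inspect only the algorithm's alarms — not the whole recording —
and relabel each as seizure, artifact or other physiological event.
Exported review packages carry the display settings the readers used
(10 s EEG window at 70 µV/cm, heart rate in a 10 min window) as
metadata so any viewer can honour them; no GUI is provided here.

When an alarm overlaps a ground-truth seizure (a correct detection),
the merged annotation file substitutes the alarm interval for the
ground-truth one, keeping the original extent in provenance columns.
Substitution never changes an alarm's overlap status, so scoring the
merged package against the original ground truth matches scoring the
raw alarms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .events import AnnotationEvent, DetectionEvent, overlaps
from .io import Recording

READER_LABELS = ("seizure", "artifact", "other")
REVIEW_SETUPS = ("eeg", "eeg+ecg")


@dataclass(frozen=True)
class DisplayContext:
    """Viewer settings for the review session."""

    eeg_window_s: float = 10.0
    hr_window_s: float = 600.0
    eeg_scale_uv_per_cm: float = 70.0


@dataclass(frozen=True)
class ReviewItem:
    alarm_id: str
    start_s: float
    end_s: float
    modality: str
    display_context: DisplayContext = DisplayContext()


@dataclass(frozen=True)
class ReaderLabel:
    alarm_id: str
    label: str
    reader_id: str
    setup: str = "eeg"
    review_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.label not in READER_LABELS:
            raise ValueError(f"unknown reader label {self.label!r}")
        if self.setup not in REVIEW_SETUPS:
            raise ValueError(f"unknown review setup {self.setup!r}")


def _alarm_id(index: int, ev: DetectionEvent) -> str:
    """Stable id: position in the alarm list plus modality and interval."""
    return (f"a{index:04d}-{ev.modality}-{int(round(ev.start_s * 1000))}-"
            f"{int(round(ev.end_s * 1000))}")


def prepare_review(recording: Recording, alarms: list[DetectionEvent],
                   ground_truth: list[AnnotationEvent],
                   display: DisplayContext = DisplayContext()
                   ) -> tuple[list[ReviewItem], pd.DataFrame]:
    """Build review items plus the merged annotation table.

    The merged table holds one row per alarm (source ``algorithm``) and
    one per ground-truth seizure that no alarm overlaps (the algorithm's
    misses, kept as ``ground_truth`` rows).  For correct detections the
    ground-truth interval is replaced by the alarm interval; the original
    extent is preserved in ``orig_start_s``/``orig_end_s``.  Alarm ids
    are derived from modality and millisecond interval, hence stable.
    """
    duration = recording.duration_s
    for al in alarms:
        if al.start_s < 0 or al.end_s > duration + 1e-9:
            raise ValueError(
                f"alarm [{al.start_s}, {al.end_s}) outside recording of "
                f"{duration:.1f}s")
    items = [ReviewItem(_alarm_id(i, al), al.start_s, al.end_s, al.modality,
                        display) for i, al in enumerate(alarms)]

    truth = [ev for ev in ground_truth if ev.label == "seizure"]
    rows = []
    for i, al in enumerate(alarms):
        matched = [ev for ev in truth
                   if overlaps(al.start_s, al.end_s, ev.start_s, ev.end_s)]
        orig = matched[0] if matched else None
        rows.append({
            "alarm_id": _alarm_id(i, al), "start_s": al.start_s,
            "end_s": al.end_s, "label": "alarm", "source": "algorithm",
            "modality": al.modality,
            "orig_start_s": orig.start_s if orig else float("nan"),
            "orig_end_s": orig.end_s if orig else float("nan"),
        })
    for ev in truth:
        if not any(overlaps(al.start_s, al.end_s, ev.start_s, ev.end_s)
                   for al in alarms):
            rows.append({
                "alarm_id": "", "start_s": ev.start_s, "end_s": ev.end_s,
                "label": "seizure", "source": "ground_truth", "modality": "",
                "orig_start_s": ev.start_s, "orig_end_s": ev.end_s,
            })
    merged = pd.DataFrame(rows, columns=["alarm_id", "start_s", "end_s",
                                         "label", "source", "modality",
                                         "orig_start_s", "orig_end_s"])
    merged = merged.sort_values("start_s", kind="stable").reset_index(drop=True)
    return items, merged


def ingest_reader_labels(path, review_items: list[ReviewItem]
                         ) -> list[ReaderLabel]:
    """Read a reader relabel CSV and match rows to review items.

    Header: ``alarm_id,label,reader_id[,setup][,review_time_s]``.
    Unknown alarm ids or labels raise with the offending row; duplicate
    (alarm, reader, setup) rows keep the last one with a warning.
    """
    df = pd.read_csv(path)
    required = ["alarm_id", "label", "reader_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    known = {it.alarm_id for it in review_items}
    out: dict[tuple, ReaderLabel] = {}
    for idx, row in df.iterrows():
        if str(row["alarm_id"]) not in known:
            raise ValueError(
                f"{path}: row {idx + 1}: unknown alarm_id {row['alarm_id']!r}")
        try:
            label = ReaderLabel(
                alarm_id=str(row["alarm_id"]), label=str(row["label"]),
                reader_id=str(row["reader_id"]),
                setup=str(row.get("setup", "eeg")) if "setup" in df.columns
                else "eeg",
                review_time_s=float(row["review_time_s"])
                if "review_time_s" in df.columns
                and pd.notna(row["review_time_s"]) else None,
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx + 1}: {exc}") from None
        key = (label.alarm_id, label.reader_id, label.setup)
        if key in out:
            warnings.warn(f"duplicate label for alarm {label.alarm_id} by "
                          f"reader {label.reader_id}; keeping the last row")
        out[key] = label
    return list(out.values())


def summarize_review(labels: list[ReaderLabel],
                     recording_duration_s: float | None = None) -> dict:
    """Per-(reader, setup) label histograms and review-time summary.

    Review times are summed per session and, when the recording duration
    is known, normalized to minutes per 24 h of recording; the summary
    reports mean and median over sessions.  Sessions without timing data
    simply contribute no timing fields.
    """
    sessions: dict[tuple[str, str], dict] = {}
    for lab in labels:
        key = (lab.reader_id, lab.setup)
        sess = sessions.setdefault(key, {"counts": {l: 0 for l in READER_LABELS},
                                         "review_time_s": 0.0, "timed": False})
        sess["counts"][lab.label] += 1
        if lab.review_time_s is not None:
            sess["review_time_s"] += lab.review_time_s
            sess["timed"] = True

    out: dict = {"sessions": {}}
    rates = []
    for (reader, setup), sess in sorted(sessions.items()):
        entry: dict = {"reader_id": reader, "setup": setup,
                       "counts": sess["counts"],
                       "n_labels": sum(sess["counts"].values())}
        if sess["timed"]:
            entry["review_time_s"] = sess["review_time_s"]
            if recording_duration_s:
                per24 = sess["review_time_s"] / recording_duration_s * 86400 / 60
                entry["review_min_per_24h"] = per24
                rates.append(per24)
        out["sessions"][f"{reader}/{setup}"] = entry
    if rates:
        import numpy as np
        out["mean_review_min_per_24h"] = float(np.mean(rates))
        out["median_review_min_per_24h"] = float(np.median(rates))
    return out
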