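"""Event-based scoring of seizure alarms and rater statistics.

Scoring is at the event level: an alarm is a true positive when it
overlaps (non-empty half-open intersection with) any ground-truth
seizure, a false positive otherwise; a seizure is *detected* when at
least one alarm overlaps it and *missed* otherwise.  Both counts matter
and they differ: several alarms can hit the same seizure, so the number
of TP detections can exceed the number of detected seizures.  The four
reported metrics are

    sensitivity = detected / (detected + missed)
    FD/24h      = 86400 * FP / D          (D = recording seconds)
    PPV         = TP / (TP + FP)
    F1          = 2 * sens * PPV / (sens + PPV)

Undefined ratios (0/0) are flagged as NaN with the field name recorded,
never silently coerced to 0.

For the semi-automated review experiment, readers relabel only the
algorithm's alarms, so seizures the algorithm never flagged are outside
the reader's reach and are excluded from the reader's denominators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sstats

from .events import AnnotationEvent, DetectionEvent, overlaps


@dataclass(frozen=True)
class MatchResult:
    """Raw event-matching counts for one scored unit (recording or pool)."""

    tp_detections: int
    fp_detections: int
    detected_seizures: int
    missed_seizures: int
    duration_s: float

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            self.tp_detections + other.tp_detections,
            self.fp_detections + other.fp_detections,
            self.detected_seizures + other.detected_seizures,
            self.missed_seizures + other.missed_seizures,
            self.duration_s + other.duration_s,
        )


@dataclass
class ScoreReport:
    sensitivity: float
    fd_per_24h: float
    ppv: float
    f1: float
    match: MatchResult | None = None
    undefined: frozenset[str] = frozenset()
    strata: dict[str, "ScoreReport"] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"sensitivity": self.sensitivity, "fd_per_24h": self.fd_per_24h,
             "ppv": self.ppv, "f1": self.f1,
             "undefined": sorted(self.undefined)}
        if self.match is not None:
            d.update(tp=self.match.tp_detections, fp=self.match.fp_detections,
                     detected=self.match.detected_seizures,
                     missed=self.match.missed_seizures,
                     duration_s=self.match.duration_s)
        if self.strata:
            d["strata"] = {k: v.as_dict() for k, v in self.strata.items()}
        return d


def match_events(alarms: Sequence[DetectionEvent | AnnotationEvent],
                 ground_truth: Sequence[AnnotationEvent],
                 duration_s: float) -> MatchResult:
    """Count TP/FP alarms and detected/missed seizures by interval overlap."""
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    truth = [ev for ev in ground_truth if getattr(ev, "label", "seizure") == "seizure"]
    tstarts = np.array([ev.start_s for ev in truth])
    tends = np.array([ev.end_s for ev in truth])
    tp = fp = 0
    hit = np.zeros(len(truth), dtype=bool)
    for al in alarms:
        m = (al.start_s < tends) & (tstarts < al.end_s)
        if m.any():
            tp += 1
            hit |= m
        else:
            fp += 1
    return MatchResult(tp_detections=tp, fp_detections=fp,
                       detected_seizures=int(hit.sum()),
                       missed_seizures=int(len(truth) - hit.sum()),
                       duration_s=float(duration_s))


def _ratio(num: float, den: float, name: str,
           undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return math.nan
    return num / den


def harmonic_f1(sensitivity: float, ppv: float) -> float:
    """F1 = 2*sens*PPV/(sens+PPV); 0 when either term is 0."""
    if sensitivity + ppv == 0:
        return 0.0
    return 2.0 * sensitivity * ppv / (sensitivity + ppv)


def compute_metrics(match: MatchResult) -> ScoreReport:
    """The four event-level metrics from raw counts, with 0/0 flagged."""
    undef: set[str] = set()
    sens = _ratio(match.detected_seizures,
                  match.detected_seizures + match.missed_seizures,
                  "sensitivity", undef)
    ppv = _ratio(match.tp_detections,
                 match.tp_detections + match.fp_detections, "ppv", undef)
    fd = 86400.0 * match.fp_detections / match.duration_s
    if math.isnan(sens) or math.isnan(ppv):
        undef.add("f1")
        f1 = math.nan
    else:
        f1 = harmonic_f1(sens, ppv)
    return ScoreReport(sensitivity=sens, fd_per_24h=fd, ppv=ppv, f1=f1,
                       match=match, undefined=frozenset(undef))


def detection_sensitivity(match: MatchResult) -> float:
    """TP detections over (TP detections + missed seizures); differs from
    ``sensitivity`` when one seizure attracts several alarms."""
    den = match.tp_detections + match.missed_seizures
    return math.nan if den == 0 else match.tp_detections / den


def score_reader(reader_labels: Iterable,
                 alarms: Mapping[str, DetectionEvent],
                 ground_truth: Sequence[AnnotationEvent],
                 duration_s: float | None = None) -> ScoreReport:
    """Score a reader's relabelling of the algorithm's alarms.

    ``reader_labels`` yields objects (or tuples) with ``alarm_id`` and
    ``label`` in {seizure, artifact, other}.  TP: labelled seizure and
    the alarm overlaps ground truth; FP: labelled seizure, no overlap;
    FN: alarm overlaps ground truth but was not labelled seizure.
    Seizures the algorithm missed never enter these counts.
    """
    truth = [ev for ev in ground_truth if ev.label == "seizure"]
    tp = fp = fn = 0
    for item in reader_labels:
        if isinstance(item, tuple):
            alarm_id, label = item[0], item[1]
        else:
            alarm_id, label = item.alarm_id, item.label
        if alarm_id not in alarms:
            raise ValueError(f"reader label references unknown alarm {alarm_id!r}")
        if label not in ("seizure", "artifact", "other"):
            raise ValueError(f"unknown reader label {label!r}")
        al = alarms[alarm_id]
        hit = any(overlaps(al.start_s, al.end_s, ev.start_s, ev.end_s)
                  for ev in truth)
        if label == "seizure" and hit:
            tp += 1
        elif label == "seizure":
            fp += 1
        elif hit:
            fn += 1
    undef: set[str] = set()
    sens = _ratio(tp, tp + fn, "sensitivity", undef)
    ppv = _ratio(tp, tp + fp, "ppv", undef)
    if duration_s:
        fd = 86400.0 * fp / duration_s
    else:
        undef.add("fd_per_24h")
        fd = math.nan
    f1 = math.nan if (math.isnan(sens) or math.isnan(ppv)) else harmonic_f1(sens, ppv)
    if math.isnan(f1):
        undef.add("f1")
    # reader counts reuse MatchResult fields: detected == TP alarms here
    match = MatchResult(tp, fp, tp, fn, duration_s or 0.0)
    return ScoreReport(sensitivity=sens, fd_per_24h=fd, ppv=ppv, f1=f1,
                       match=match, undefined=frozenset(undef))


@dataclass
class CohortRecord:
    """Per-recording inputs for stratified scoring."""

    patient_id: str
    alarms: list[DetectionEvent]
    ground_truth: list[AnnotationEvent]
    duration_s: float
    localization: str | None = None
    tachy_status: str | None = None


def score_cohort(records: Sequence[CohortRecord]) -> ScoreReport:
    """Pool matching counts over a cohort and compute global metrics."""
    pooled = None
    for r in records:
        m = match_events(r.alarms, r.ground_truth, r.duration_s)
        pooled = m if pooled is None else pooled + m
    if pooled is None:
        raise ValueError("empty cohort")
    return compute_metrics(pooled)


def stratify(records: Sequence[CohortRecord],
             by: tuple[str, ...] = ("localization", "tachy_status")
             ) -> dict[str, dict[str, ScoreReport]]:
    """Metrics per stratum (seizure-onset localization, tachycardia
    response), each stratum pooled over its recordings.  Strata form a
    partition of the cohort, so per-stratum counts sum to the global
    counts."""
    out: dict[str, dict[str, ScoreReport]] = {}
    for attr in by:
        groups: dict[str, list[CohortRecord]] = {}
        for r in records:
            key = getattr(r, attr)
            if key is None:
                key = "unknown"
            groups.setdefault(key, []).append(r)
        out[attr] = {k: score_cohort(v) for k, v in sorted(groups.items())}
    return out


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected inter-rater agreement.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the product of the two
    raters' marginals.  When p_e == 1 (both raters constant): 1.0 if the
    observed agreement is also perfect, else NaN with a warning.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("need at least one paired label")
    cats = sorted(set(a) | set(b), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    n = len(a)
    table = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_e >= 1.0 - 1e-12:
        if p_o >= 1.0 - 1e-12:
            return 1.0
        warnings.warn("kappa undefined: chance agreement is 1 with imperfect "
                      "observed agreement")
        return math.nan
    return float((p_o - p_e) / (1.0 - p_e))


def mcnemar(b: int, c: int, exact_threshold: int = 25) -> tuple[float, float]:
    """McNemar's test from discordant-pair counts.

    Exact two-sided binomial when b + c < ``exact_threshold``, else the
    continuity-corrected chi-square with 1 df.  Returns (statistic, p).
    b = c (including the degenerate 0/0 case) gives p = 1 by symmetry.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 0.0, 1.0
    if n < exact_threshold:
        stat = float(min(b, c))
        p = sstats.binomtest(int(min(b, c)), n, 0.5, alternative="two-sided").pvalue
        return stat, float(min(1.0, p))
    stat = (abs(b - c) - 1.0) ** 2 / n
    return float(stat), float(sstats.chi2.sf(stat, df=1))


def mcnemar_from_sequences(correct_a: Sequence[bool],
                           correct_b: Sequence[bool],
                           exact_threshold: int = 25) -> tuple[float, float]:
    """Build the discordant counts from two paired correctness sequences
    (b: A right / B wrong; c: A wrong / B right) and run the test."""
    if len(correct_a) != len(correct_b):
        raise ValueError("sequences must be paired (equal length)")
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    return mcnemar(int((a & ~bb).sum()), int((~a & bb).sum()), exact_threshold)
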