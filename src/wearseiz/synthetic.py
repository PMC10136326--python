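"""Seeded synthetic wearable recordings for developing and testing the
detectors without access to clinical data.

The generator emulates the statistical structure the detectors rely on,
not the physiology behind it:

* interictal bte-EEG is zero-mean 1/f-weighted noise;
* an ictal discharge is a theta-range (3-8 Hz) rhythm whose amplitude
  ramps linearly from 0.3x to 1x over the seizure, injected at full
  strength on the cross-head channel and attenuated on the ipsilateral
  one (focal cohorts show the rhythm best cross-head);
* muscle-artifact episodes are high-amplitude 20-35 Hz bursts, the part
  of the band-passed spectrum real chewing/movement artifacts occupy;
* heart rate is a smooth baseline with bounded wander plus a configurable
  peri-ictal rise (>= 20 BPM makes the patient a tachycardia responder)
  that ramps up at seizure onset and decays exponentially afterwards;
* ECG is a fixed PQRST template laid down at beat times integrated from
  the heart-rate profile, so the true R-peak times are known exactly and
  serve as ground truth for the R-peak detectors.

Everything is a pure function of (config, seed).  A packaged cohort
table (42 patients, 221 seizures, 23 tachycardia responders) mirrors the
clinical population the framework targets and drives stratified tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .ecg import HeartRateSeries
from .events import AnnotationEvent
from .io import (ROLE_ECG, ROLE_EEG_CROSS, ROLE_EEG_IPSI, ROLE_HR, Channel,
                 Recording)

IPSI_ATTENUATION = 0.6  # ictal rhythm scaling on the ipsilateral channel


@dataclass(frozen=True)
class PatientMetadata:
    """One row of the packaged cohort table."""

    patient_id: str
    n_seizures: int
    seizure_types: dict[str, int]
    localization: dict[str, int]
    lateralization: dict[str, int]
    ictal_tachycardia: str  # yes | intermediate | no

    def __post_init__(self) -> None:
        if self.n_seizures < 1:
            raise ValueError("n_seizures must be >= 1")
        for name in ("seizure_types", "localization", "lateralization"):
            ms = getattr(self, name)
            if sum(ms.values()) != self.n_seizures:
                raise ValueError(
                    f"{name} multiset of patient {self.patient_id} sums to "
                    f"{sum(ms.values())}, expected {self.n_seizures}"
                )

    @property
    def dominant_localization(self) -> str:
        return max(self.localization.items(), key=lambda kv: (kv[1], kv[0]))[0]


def _parse_multiset(text: str) -> dict[str, int]:
    out = {}
    for part in str(text).split(";"):
        key, _, count = part.partition(":")
        out[key.strip()] = int(count)
    return out


def table1_metadata() -> list[PatientMetadata]:
    """The packaged 42-patient cohort table (fixture data)."""
    with resources.files("wearseiz.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        PatientMetadata(
            patient_id=str(row.patient_id),
            n_seizures=int(row.n_seizures),
            seizure_types=_parse_multiset(row.seizure_types),
            localization=_parse_multiset(row.localization),
            lateralization=_parse_multiset(row.lateralization),
            ictal_tachycardia=str(row.ictal_tachycardia),
        )
        for row in df.itertuples()
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording.

    Durations are scaled to desk size; the clinical recordings the
    framework targets run for days, which changes only the amount of
    background, not its structure.
    """

    duration_s: float = 1200.0
    fs: float = 250.0
    seizure_intervals: tuple[tuple[float, float], ...] = ()
    ictal_eeg_freq: float = 6.0      # Hz, theta-range rhythmic discharge
    ictal_eeg_amp: float = 50.0      # µV
    background_amp: float = 20.0     # µV (SD of interictal EEG)
    artifact_rate: float = 6.0       # episodes per hour
    artifact_amp: float = 60.0       # µV
    artifact_guard_s: float = 30.0   # no artifacts this close to a seizure
    baseline_hr: float = 70.0        # BPM
    ictal_hr_increase: float = 25.0  # BPM; >= 20 makes a responder
    hr_ramp_s: float = 20.0
    hr_decay_s: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 40 <= self.baseline_hr <= 180:
            raise ValueError(f"baseline_hr {self.baseline_hr} outside [40, 180]")
        if self.ictal_hr_increase < 0:
            raise ValueError("ictal_hr_increase must be >= 0")
        ivs = sorted(self.seizure_intervals)
        for s, e in ivs:
            if not (0 <= s < e <= self.duration_s):
                raise ValueError(f"seizure interval [{s}, {e}) outside recording")
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError("seizure intervals overlap")


def gen_background_eeg(duration_s: float, fs: float, amp: float,
                       seed: int) -> np.ndarray:
    """Zero-mean 1/f-weighted noise with SD equal to ``amp`` (µV)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(duration_s * fs))
    if amp == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    weight = np.ones_like(freqs)
    nz = freqs > 0
    weight[nz] = 1.0 / np.sqrt(freqs[nz])
    weight[0] = 0.0  # zero mean
    x = np.fft.irfft(spec * weight, n=n)
    sd = x.std()
    return x * (amp / sd) if sd > 0 else x


def gen_ictal_eeg(interval: tuple[float, float], fs: float, freq: float,
                  amp: float, seed: int) -> np.ndarray:
    """Ramped rhythmic ictal discharge over ``interval`` (µV).

    Amplitude-modulated sinusoid rising linearly from 0.3*amp to amp,
    plus background-scale (0.15*amp) 1/f noise.  A frequency outside the
    0.5-35 Hz review passband is allowed but warned about, since display
    filtering would attenuate it.
    """
    start, end = interval
    n = int(round((end - start) * fs))
    if n <= 0:
        return np.zeros(0)
    if amp <= 0:
        raise ValueError("amp must be positive")
    if not 0.5 <= freq <= 35.0:
        warnings.warn(f"ictal frequency {freq} Hz lies outside the 0.5-35 Hz "
                      "passband and would be attenuated by display filtering")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    envelope = amp * (0.3 + 0.7 * t / (n / fs))
    phase = rng.uniform(0, 2 * np.pi)
    rhythm = envelope * np.sin(2 * np.pi * freq * t + phase)
    noise = gen_background_eeg(n / fs, fs, 0.15 * amp,
                               int(rng.integers(2 ** 31)))
    return rhythm + noise


def gen_hr_profile(config: SimulationConfig) -> HeartRateSeries:
    """1 Hz heart-rate profile: baseline + bounded wander + peri-ictal
    rise of ``ictal_hr_increase`` BPM ramping over ``hr_ramp_s`` and
    decaying exponentially (tau = ``hr_decay_s``) after seizure end."""
    rng = np.random.default_rng(config.seed + 101)
    t = np.arange(0.0, config.duration_s, 1.0)
    # bounded wander: slow sinusoids + light jitter, SD well under 2 BPM
    wander = np.zeros_like(t)
    for period, a in ((300.0, 1.3), (90.0, 0.7), (30.0, 0.4)):
        wander += a * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
    wander += 0.3 * rng.standard_normal(len(t))
    bpm = config.baseline_hr + wander
    for s, e in config.seizure_intervals:
        ramp = np.clip((t - s) / max(config.hr_ramp_s, 1e-9), 0.0, 1.0)
        shape = np.where(t < s, 0.0, np.where(t < e, ramp,
                         np.exp(-(t - e) / max(config.hr_decay_s, 1e-9))))
        bpm = bpm + config.ictal_hr_increase * shape
    return HeartRateSeries(t, bpm)


# PQRST template: (offset s, amplitude mV, gaussian width s)
_PQRST = ((-0.20, 0.12, 0.040),   # P
          (-0.025, -0.10, 0.010),  # Q
          (0.0, 1.00, 0.012),      # R
          (0.025, -0.15, 0.010),   # S
          (0.25, 0.30, 0.060))     # T


def gen_ecg(hr_profile: HeartRateSeries, fs: float,
            seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Single-lead ECG (mV) whose R-R intervals follow the heart-rate
    profile.  Returns ``(signal, true_rpeak_times_s)``.

    Beat times are integrated from the instantaneous rate (next beat one
    RR = 60/HR later, with ~5 ms timing jitter); each beat stamps a fixed
    PQRST Gaussian template, and 0.02 mV measurement noise is added.
    """
    bpm = hr_profile.bpm
    if len(bpm) and (bpm.min() < 30 or bpm.max() > 220):
        raise ValueError("heart-rate profile outside [30, 220] BPM")
    rng = np.random.default_rng(seed + 202)
    duration = float(hr_profile.times_s[-1]) + 1.0 if len(hr_profile) else 0.0
    n = int(round(duration * fs))
    sig = 0.02 * rng.standard_normal(n)
    beat_times = []
    t = 0.3  # first beat shortly after start
    while t < duration - 0.5:
        beat_times.append(t)
        hr_now = float(np.interp(t, hr_profile.times_s, bpm))
        rr = 60.0 / hr_now + rng.normal(0.0, 0.005)
        t += max(0.25, rr)
    beats = np.array(beat_times)
    tt = np.arange(n) / fs
    for off, amp, width in _PQRST:
        centers = beats + off
        lo = np.searchsorted(tt, centers - 4 * width)
        hi = np.searchsorted(tt, centers + 4 * width)
        for c, a, b in zip(centers, lo, hi):
            seg = tt[a:b] - c
            sig[a:b] += amp * np.exp(-0.5 * (seg / width) ** 2)
    return sig, beats


def _place_artifacts(rng: np.random.Generator,
                     config: SimulationConfig) -> list[tuple[float, float]]:
    n_expected = config.artifact_rate * config.duration_s / 3600.0
    n_art = rng.poisson(n_expected)
    guard = [(max(0.0, s - config.artifact_guard_s),
              min(config.duration_s, e + config.artifact_guard_s))
             for s, e in config.seizure_intervals]
    placed = []
    attempts = 0
    while len(placed) < n_art and attempts < 50 * max(n_art, 1):
        attempts += 1
        dur = rng.uniform(2.0, 6.0)
        start = rng.uniform(0.0, config.duration_s - dur)
        iv = (start, start + dur)
        clash = any(iv[0] < g1 and g0 < iv[1] for g0, g1 in guard)
        clash |= any(iv[0] < p1 + 5 and p0 - 5 < iv[1] for p0, p1 in placed)
        if not clash:
            placed.append(iv)
    return sorted(placed)


def _artifact_burst(n: int, fs: float, amp: float,
                    rng: np.random.Generator) -> np.ndarray:
    """EMG-like 20-35 Hz band-limited burst with a tapered envelope."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < 20.0) | (freqs > 35.0)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd > 0:
        x *= amp / sd
    taper = np.hanning(n) if n > 2 else np.ones(n)
    return x * taper


def gen_recording(config: SimulationConfig,
                  patient_id: str = "synthetic",
                  include_hr_channel: bool = False,
                  ) -> tuple[Recording, list[AnnotationEvent]]:
    """Generate a full synthetic recording and its ground truth.

    Two bte-EEG channels (ictal rhythm at full amplitude cross-head,
    attenuated x0.6 ipsilateral), one ECG channel following the
    heart-rate profile, optionally the 1 Hz heart-rate trace as a fourth
    channel, and one ground-truth seizure annotation per configured
    interval.  Bit-deterministic in (config, seed)."""
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    cross = gen_background_eeg(config.duration_s, fs, config.background_amp,
                               config.seed + 1)
    ipsi = gen_background_eeg(config.duration_s, fs, config.background_amp,
                              config.seed + 2)
    for k, (s, e) in enumerate(config.seizure_intervals):
        burst = gen_ictal_eeg((s, e), fs, config.ictal_eeg_freq,
                              config.ictal_eeg_amp, config.seed + 10 + k)
        i0 = int(round(s * fs))
        cross[i0:i0 + len(burst)] += burst
        ipsi[i0:i0 + len(burst)] += IPSI_ATTENUATION * burst
    art_rng = np.random.default_rng(config.seed + 3)
    for s, e in _place_artifacts(art_rng, config):
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        burst = _artifact_burst(i1 - i0, fs, config.artifact_amp, art_rng)
        cross[i0:i1] += burst
        ipsi[i0:i1] += 0.8 * _artifact_burst(i1 - i0, fs,
                                             config.artifact_amp, art_rng)
    hr = gen_hr_profile(config)
    ecg, _ = gen_ecg(hr, fs, config.seed)
    n_target = int(round(config.duration_s * fs))
    if len(ecg) < n_target:
        ecg = np.pad(ecg, (0, n_target - len(ecg)))

    channels = [
        Channel("EEG CrossHead", ROLE_EEG_CROSS, cross, fs),
        Channel("EEG Ipsi", ROLE_EEG_IPSI, ipsi, fs),
        Channel("ECG", ROLE_ECG, ecg[:n_target], fs),
    ]
    if include_hr_channel:
        channels.append(Channel("HR", ROLE_HR, hr.bpm, 1.0))
    rec = Recording(patient_id=patient_id, channels=channels)
    truth = [AnnotationEvent(s, e, "seizure", "ground_truth")
             for s, e in sorted(config.seizure_intervals)]
    return rec, truth


@dataclass(frozen=True)
class CohortMember:
    recording: Recording
    ground_truth: list[AnnotationEvent]
    config: SimulationConfig
    tachy_label: str  # responder | intermediate | nonresponder


_TACHY_INCREASE = {"responder": 25.0, "intermediate": 10.0,
                   "nonresponder": 0.0}


def default_config(seed: int, duration_s: float = 1200.0,
                   tachy: str = "responder") -> SimulationConfig:
    """The standard per-recording simulation conditions used throughout
    the test cohorts: two ~40 s seizures with seeded placement and a
    theta-range discharge frequency drawn per recording."""
    rng = np.random.default_rng(seed + 777)
    seiz = []
    for lo, hi in ((0.25, 0.40), (0.65, 0.80)):
        start = rng.uniform(lo, hi) * duration_s
        seiz.append((round(start, 1), round(start + 40.0, 1)))
    return SimulationConfig(
        duration_s=duration_s,
        seizure_intervals=tuple(seiz),
        ictal_eeg_freq=float(rng.uniform(4.0, 7.5)),
        baseline_hr=float(rng.uniform(60.0, 80.0)),
        ictal_hr_increase=_TACHY_INCREASE[tachy],
        seed=seed,
    )


def make_cohort(n_recordings: int = 10, base_seed: int = 0,
                duration_s: float = 1200.0,
                tachy: str = "responder") -> list[CohortMember]:
    """Seeded cohort of synthetic recordings (seeds base..base+n-1)."""
    members = []
    for k in range(n_recordings):
        cfg = default_config(base_seed + k, duration_s, tachy)
        rec, truth = gen_recording(cfg, patient_id=f"syn{base_seed + k:03d}")
        members.append(CohortMember(rec, truth, cfg, tachy))
    return members
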