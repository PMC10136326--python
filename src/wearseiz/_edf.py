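"""Minimal European Data Format (EDF) codec.

Implements the 16-bit EDF specification (Kemp et al., 1992): a 256-byte
fixed header, 256 bytes of header per signal, then data records of
little-endian int16 samples, channel by channel.  Supports per-channel
sampling rates via the samples-per-record field, with a fixed data-record
duration of 1 s — signals must therefore contain a whole number of
seconds.  EDF+ TAL annotation channels are out of scope.

Physical values are reconstructed as

    x = phys_min + (d - dig_min) * (phys_max - phys_min) / (dig_max - dig_min)

so a round trip is exact up to half the quantization step
(phys range / (dig range)).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np

_HDR = 256
_DIG_MIN = -32768
_DIG_MAX = 32767


@dataclass
class EdfSignal:
    label: str
    samples: np.ndarray  # physical units, float
    fs: float            # Hz, must give integer samples per 1 s record
    physical_dim: str = "uV"
    physical_min: float | None = None
    physical_max: float | None = None
    prefilter: str = ""
    transducer: str = ""


@dataclass
class EdfFile:
    signals: list[EdfSignal]
    patient_id: str = "X"
    recording_id: str = "X"
    startdate: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2000, 1, 1, 0, 0, 0)
    )


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width)


def _num(value: float, width: int) -> bytes:
    """Format a number into EDF's fixed-width ASCII field."""
    for prec in range(10, 0, -1):
        fmt = f"{value:.{prec}g}"
        if len(fmt) <= width:
            return _pad(fmt, width)
    raise ValueError(f"cannot format {value!r} in {width} ASCII characters")


def write_edf(path, edf: EdfFile) -> str:
    """Write signals to ``path`` as EDF.  Returns the path written."""
    ns = len(edf.signals)
    if ns == 0:
        raise ValueError("EDF file needs at least one signal")

    durations = []
    for sig in edf.signals:
        if not np.all(np.isfinite(sig.samples)):
            raise ValueError(f"non-finite samples in channel {sig.label!r}")
        spr = sig.fs * 1.0
        if spr <= 0 or abs(spr - round(spr)) > 1e-9:
            raise ValueError(
                f"channel {sig.label!r}: fs={sig.fs} Hz must be a positive "
                "integer (1 s data records)"
            )
        n = len(sig.samples)
        if n % int(round(spr)) != 0:
            raise ValueError(
                f"channel {sig.label!r}: length {n} is not a whole number of "
                f"seconds at fs={sig.fs}"
            )
        durations.append(n / spr)
    if len({int(round(d)) for d in durations}) != 1:
        raise ValueError(f"channels disagree on duration: {durations}")
    n_records = int(round(durations[0]))

    header = bytearray()
    header += _pad("0", 8)
    header += _pad(edf.patient_id, 80)
    header += _pad(edf.recording_id, 80)
    header += _pad(edf.startdate.strftime("%d.%m.%y"), 8)
    header += _pad(edf.startdate.strftime("%H.%M.%S"), 8)
    header += _pad(str(_HDR * (ns + 1)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)
    header += _pad(str(ns), 4)

    phys_ranges = []
    for sig in edf.signals:
        lo, hi = sig.physical_min, sig.physical_max
        if lo is None or hi is None:
            smin = float(np.min(sig.samples)) if len(sig.samples) else -1.0
            smax = float(np.max(sig.samples)) if len(sig.samples) else 1.0
            # symmetric range with 1% headroom so extremes never clip
            bound = max(abs(smin), abs(smax), 1e-6) * 1.01
            lo, hi = -bound, bound
        if not hi > lo:
            raise ValueError(f"channel {sig.label!r}: physical_max must exceed physical_min")
        phys_ranges.append((lo, hi))

    for attr, width in (
        ("label", 16), ("transducer", 80), ("physical_dim", 8),
    ):
        for sig in edf.signals:
            header += _pad(getattr(sig, attr), width)
    for lo, _ in phys_ranges:
        header += _num(lo, 8)
    for _, hi in phys_ranges:
        header += _num(hi, 8)
    for _ in edf.signals:
        header += _num(_DIG_MIN, 8)
    for _ in edf.signals:
        header += _num(_DIG_MAX, 8)
    for sig in edf.signals:
        header += _pad(sig.prefilter, 80)
    for sig in edf.signals:
        header += _pad(str(int(round(sig.fs))), 8)
    for _ in edf.signals:
        header += _pad("", 32)

    digital = []
    for sig, (lo, hi) in zip(edf.signals, phys_ranges):
        scale = (hi - lo) / (_DIG_MAX - _DIG_MIN)
        d = np.round((np.asarray(sig.samples, dtype=float) - lo) / scale) + _DIG_MIN
        d = np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2")
        digital.append(d)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        sprs = [int(round(sig.fs)) for sig in edf.signals]
        for rec in range(n_records):
            for d, spr in zip(digital, sprs):
                fh.write(d[rec * spr:(rec + 1) * spr].tobytes())
    return str(path)


def read_edf(path) -> EdfFile:
    """Read an EDF/EDF+C file.  Raises ValueError on malformed input."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HDR:
        raise ValueError(f"{path}: too short to be an EDF file")

    def f(off: int, width: int) -> str:
        return raw[off:off + width].decode("ascii", errors="replace").strip()

    version = f(0, 8)
    if version not in ("0", "0\x00"):
        raise ValueError(f"{path}: not an EDF file (version field {version!r})")
    patient_id = f(8, 80)
    recording_id = f(88, 80)
    date_s, time_s = f(168, 8), f(176, 8)
    try:
        startdate = _dt.datetime.strptime(date_s + " " + time_s, "%d.%m.%y %H.%M.%S")
    except ValueError:
        startdate = _dt.datetime(2000, 1, 1)
    try:
        n_records = int(f(236, 8))
        record_dur = float(f(244, 8))
        ns = int(f(252, 4))
    except ValueError as exc:
        raise ValueError(f"{path}: corrupt EDF header: {exc}") from None
    if ns <= 0:
        raise ValueError(f"{path}: no signals in header")
    need = _HDR * (ns + 1)
    if len(raw) < need:
        raise ValueError(f"{path}: truncated signal headers")

    def col(idx: int, width: int, base: int) -> str:
        return raw[base + idx * width: base + (idx + 1) * width].decode(
            "ascii", errors="replace").strip()

    base = _HDR
    labels = [col(i, 16, base) for i in range(ns)]; base += 16 * ns
    transducers = [col(i, 80, base) for i in range(ns)]; base += 80 * ns
    dims = [col(i, 8, base) for i in range(ns)]; base += 8 * ns
    try:
        pmins = [float(col(i, 8, base)) for i in range(ns)]; base += 8 * ns
        pmaxs = [float(col(i, 8, base)) for i in range(ns)]; base += 8 * ns
        dmins = [int(float(col(i, 8, base))) for i in range(ns)]; base += 8 * ns
        dmaxs = [int(float(col(i, 8, base))) for i in range(ns)]; base += 8 * ns
    except ValueError as exc:
        raise ValueError(f"{path}: corrupt signal header: {exc}") from None
    prefilters = [col(i, 80, base) for i in range(ns)]; base += 80 * ns
    sprs = [int(float(col(i, 8, base))) for i in range(ns)]; base += 8 * ns
    base += 32 * ns  # reserved

    rec_len = sum(sprs)
    data = np.frombuffer(raw[need:], dtype="<i2")
    if n_records < 0:  # -1 allowed: infer from file size
        n_records = len(data) // rec_len if rec_len else 0
    if len(data) < n_records * rec_len:
        raise ValueError(f"{path}: data section shorter than header promises")
    data = data[: n_records * rec_len].reshape(n_records, rec_len)

    signals = []
    off = 0
    for i in range(ns):
        chunk = data[:, off:off + sprs[i]].reshape(-1).astype(float)
        off += sprs[i]
        drange = dmaxs[i] - dmins[i]
        if drange <= 0 or not math.isfinite(pmaxs[i] - pmins[i]):
            raise ValueError(f"{path}: invalid calibration for channel {labels[i]!r}")
        scale = (pmaxs[i] - pmins[i]) / drange
        phys = pmins[i] + (chunk - dmins[i]) * scale
        signals.append(EdfSignal(
            label=labels[i], samples=phys, fs=sprs[i] / record_dur,
            physical_dim=dims[i], physical_min=pmins[i], physical_max=pmaxs[i],
            prefilter=prefilters[i], transducer=transducers[i],
        ))
    return EdfFile(signals=signals, patient_id=patient_id,
                   recording_id=recording_id, startdate=startdate)
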