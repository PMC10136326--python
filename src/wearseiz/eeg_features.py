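"""Windowed feature bank for the two-channel behind-the-ear EEG detector.

Exactly 67 features per window, drawn from four families:

* **time** (11 per channel x 2 = 22): mean absolute amplitude, RMS,
  peak-to-peak, line length, zero crossings, skewness, kurtosis, the
  Hjorth triple (activity, mobility, complexity) and mean Teager energy.
* **frequency** (9 per channel x 2 = 18): relative power in the delta
  (0.5-4 Hz), theta (4-8), alpha (8-13), beta (13-20) and high (20-35)
  bands, 95% spectral edge frequency, peak frequency, spectral centroid,
  and log total band power.
* **entropy** (4 per channel x 2 = 8): sample entropy (m=2, r=0.2 SD),
  normalized spectral entropy, normalized permutation entropy (order 3)
  and SVD (embedding) entropy.
* **asymmetry** (19, cross-channel): per-band relative-power difference
  (5, antisymmetric under channel swap), per-band log power ratio
  (5, antisymmetric), per-band power asymmetry index (Pc-Pi)/(Pc+Pi)
  (5, antisymmetric), log RMS ratio (antisymmetric), log line-length
  ratio (antisymmetric), zero-crossing difference (antisymmetric) and
  maximum normalized cross-correlation within +-50 ms (symmetric).

Scale behaviour is documented per feature: relative powers, spectral
edge/peak/centroid, Hjorth mobility/complexity, all entropies, and all
ratio/index asymmetry features are invariant to a common amplitude
rescaling; amplitude features (RMS, line length, ...) scale with it.

Degenerate (all-constant) windows use fixed conventions: amplitude and
slope features are 0, relative band powers are uniform (1/5), spectral
edge/peak/centroid are 0 and entropies are 0 (spectral entropy 1, since
a uniform spectrum is maximally flat by the same convention).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .segmentation import WindowGrid, window_view

BANDS = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 20.0),
    ("high", 20.0, 35.0),
)

_CHANNEL_TAGS = ("cross", "ipsi")


class FeatureError(ValueError):
    """Raised when a window cannot be featurized (e.g. NaN input)."""


def _per_channel_names() -> list[tuple[str, str]]:
    time_feats = ["mean_abs", "rms", "peak_to_peak", "line_length",
                  "zero_crossings", "skewness", "kurtosis",
                  "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
                  "teager_energy"]
    freq_feats = [f"relpow_{b}" for b, _, _ in BANDS] + [
        "spectral_edge95", "peak_freq", "spectral_centroid", "log_total_power"]
    ent_feats = ["sample_entropy", "spectral_entropy",
                 "permutation_entropy", "svd_entropy"]
    out = []
    for tag in _CHANNEL_TAGS:
        out += [(f"{tag}_{f}", "time") for f in time_feats]
        out += [(f"{tag}_{f}", "frequency") for f in freq_feats]
        out += [(f"{tag}_{f}", "entropy") for f in ent_feats]
    return out


def _asymmetry_names() -> list[tuple[str, str]]:
    names = []
    names += [(f"asym_relpow_diff_{b}", "asymmetry") for b, _, _ in BANDS]
    names += [(f"asym_logpow_ratio_{b}", "asymmetry") for b, _, _ in BANDS]
    names += [(f"asym_pow_index_{b}", "asymmetry") for b, _, _ in BANDS]
    names += [("asym_log_rms_ratio", "asymmetry"),
              ("asym_log_linelength_ratio", "asymmetry"),
              ("asym_zero_crossing_diff", "asymmetry"),
              ("asym_max_xcorr", "asymmetry")]
    return names


_ALL = _per_channel_names() + _asymmetry_names()
FEATURE_NAMES: tuple[str, ...] = tuple(n for n, _ in _ALL)
FEATURE_FAMILIES: dict[str, str] = dict(_ALL)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 67, N_FEATURES

#: features invariant under a common positive rescaling of both channels
SCALE_INVARIANT: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES
    if any(k in n for k in (
        "relpow", "spectral_edge", "peak_freq", "spectral_centroid",
        "hjorth_mobility", "hjorth_complexity", "entropy",
        "zero_crossings", "asym_")))


def _hjorth(win: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    var0 = np.var(win, axis=1)
    d1 = np.diff(win, axis=1)
    d2 = np.diff(d1, axis=1)
    var1 = np.var(d1, axis=1)
    var2 = np.var(d2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mob = np.sqrt(np.where(var0 > 0, var1 / np.where(var0 > 0, var0, 1), 0.0))
        mob1 = np.sqrt(np.where(var1 > 0, var2 / np.where(var1 > 0, var1, 1), 0.0))
        comp = np.where(mob > 0, mob1 / np.where(mob > 0, mob, 1), 0.0)
    return var0, mob, comp


def _band_powers(win: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray,
                                                      np.ndarray, np.ndarray]:
    """Per-window periodogram band powers.

    Returns (band_powers [n,5], total power in 0.5-35 [n], spectral
    edge/peak/centroid stacked [n,3], psd_normalized_entropy [n])."""
    n = win.shape[1]
    x = win - win.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(x * np.hanning(n), axis=1)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    inband = (freqs >= 0.5) & (freqs < 35.0)
    p_in = spec[:, inband]
    f_in = freqs[inband]
    total = p_in.sum(axis=1)
    bp = np.empty((win.shape[0], len(BANDS)))
    for j, (_, lo, hi) in enumerate(BANDS):
        sel = (f_in >= lo) & (f_in < hi)
        bp[:, j] = p_in[:, sel].sum(axis=1)

    ok = total > 0
    tot_safe = np.where(ok, total, 1.0)
    # 95% spectral edge
    csum = np.cumsum(p_in, axis=1) / tot_safe[:, None]
    edge_idx = np.argmax(csum >= 0.95, axis=1)
    edge = np.where(ok, f_in[edge_idx], 0.0)
    peak = np.where(ok, f_in[np.argmax(p_in, axis=1)], 0.0)
    centroid = np.where(ok, (p_in * f_in[None, :]).sum(axis=1) / tot_safe, 0.0)
    # normalized spectral entropy over the in-band periodogram
    pn = p_in / tot_safe[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(pn > 0, pn * np.log(pn), 0.0), axis=1)
    spec_ent = np.where(ok, h / np.log(p_in.shape[1]), 1.0)
    return bp, total, np.stack([edge, peak, centroid], axis=1), spec_ent


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """SampEn(m, r) with r = r_factor * SD(x); degenerate windows give 0.

    The full pairwise Chebyshev distance matrix is built once and reused
    for template lengths m and m+1 (windows are short, so the O(n^2)
    memory is a few hundred kB)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std()
    if n < m + 2 or sd == 0:
        return 0.0
    r = r_factor * sd
    d = np.abs(x[:, None] - x[None, :])
    dm = d[: n - m, : n - m]
    for k in range(1, m):
        dm = np.maximum(dm, d[k: n - m + k, k: n - m + k])
    bmat = dm <= r
    # template pairs for m+1 extend the same embeddings by one sample
    amat = np.maximum(dm, d[m:n, m:n]) <= r
    nb = (bmat.sum() - bmat.shape[0]) / 2.0  # exclude self-matches
    na = (amat.sum() - amat.shape[0]) / 2.0
    if nb == 0:
        return 0.0
    if na == 0:
        na = 0.5  # continuity correction for empty (m+1)-match counts
    return float(-np.log(na / nb))


def _sample_entropy_batch(win: np.ndarray, decimate: int) -> np.ndarray:
    return np.array([sample_entropy(w[::decimate]) for w in win])


def _permutation_entropy(win: np.ndarray, order: int = 3) -> np.ndarray:
    """Normalized permutation entropy per window, order-3 motifs."""
    n, L = win.shape
    if L < order:
        return np.zeros(n)
    emb = np.stack([win[:, k: L - order + 1 + k] for k in range(order)], axis=2)
    ranks = np.argsort(np.argsort(emb, axis=2, kind="stable"), axis=2)
    codes = (ranks * (order ** np.arange(order))[None, None, :]).sum(axis=2)
    n_codes = order ** order
    ent = np.zeros(n)
    flat = np.sum(np.ptp(emb, axis=2) == 0, axis=1) == emb.shape[1]
    for i in range(n):
        counts = np.bincount(codes[i], minlength=n_codes).astype(float)
        p = counts[counts > 0] / counts.sum()
        ent[i] = -(p * np.log(p)).sum() / np.log(math.factorial(order)) \
            if len(p) > 1 else 0.0
    ent[flat] = 0.0
    return np.clip(ent, 0.0, 1.0)


def _svd_entropy(win: np.ndarray, dim: int = 10) -> np.ndarray:
    n, L = win.shape
    out = np.zeros(n)
    if L <= dim:
        return out
    for i in range(n):
        w = win[i]
        if np.ptp(w) == 0:
            continue
        Y = np.lib.stride_tricks.sliding_window_view(w, dim)
        g = Y.T @ Y
        ev = np.linalg.eigvalsh(g)
        ev = ev[ev > 1e-12 * ev.max()] if ev.max() > 0 else ev
        p = ev / ev.sum()
        out[i] = -(p * np.log(p)).sum() / np.log(dim)
    return out


def _channel_features(win: np.ndarray, fs: float,
                      decimate: int) -> tuple[np.ndarray, dict]:
    """(n_windows, 24) feature block for one channel plus intermediates
    reused by the asymmetry family."""
    n = win.shape[0]
    mean_abs = np.abs(win).mean(axis=1)
    rms = np.sqrt((win ** 2).mean(axis=1))
    ptp = np.ptp(win, axis=1)
    line_length = np.abs(np.diff(win, axis=1)).sum(axis=1)
    centered = win - win.mean(axis=1, keepdims=True)
    zc = (np.diff(np.signbit(centered), axis=1) != 0).sum(axis=1).astype(float)
    sd = win.std(axis=1)
    flat = sd == 0
    skew = np.where(flat, 0.0, stats.skew(win, axis=1, bias=True))
    kurt = np.where(flat, 0.0, stats.kurtosis(win, axis=1, bias=True))
    act, mob, comp = _hjorth(win)
    teager = np.zeros(n)
    if win.shape[1] >= 3:
        tk = win[:, 1:-1] ** 2 - win[:, :-2] * win[:, 2:]
        teager = tk.mean(axis=1)

    bp, total, epc, spec_ent = _band_powers(win, fs)
    ok = total > 0
    relpow = np.where(ok[:, None], bp / np.where(ok, total, 1.0)[:, None],
                      1.0 / len(BANDS))
    log_total = np.where(ok, np.log(np.where(ok, total, 1.0)), 0.0)

    samp = _sample_entropy_batch(win, decimate)
    perm = _permutation_entropy(win)
    svd = _svd_entropy(win)

    block = np.column_stack([
        mean_abs, rms, ptp, line_length, zc, skew, kurt, act, mob, comp,
        teager,
        relpow, epc[:, 0], epc[:, 1], epc[:, 2], log_total,
        samp, spec_ent, perm, svd,
    ])
    aux = {"relpow": relpow, "bandpow": bp, "rms": rms,
           "line_length": line_length, "zc": zc}
    return block, aux


def _max_xcorr(a: np.ndarray, b: np.ndarray, fs: float,
               max_lag_s: float = 0.05) -> np.ndarray:
    """Max normalized cross-correlation within +-max_lag_s, per window."""
    n = a.shape[0]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    lag = int(round(max_lag_s * fs))
    out = np.zeros(n)
    denom = na * nb
    valid = denom > 0
    best = np.full(n, -np.inf)
    L = a.shape[1]
    for k in range(-lag, lag + 1):
        if k >= 0:
            c = (ac[:, k:] * bc[:, : L - k]).sum(axis=1)
        else:
            c = (ac[:, : L + k] * bc[:, -k:]).sum(axis=1)
        best = np.maximum(best, c)
    out[valid] = best[valid] / denom[valid]
    return np.clip(out, -1.0, 1.0)


def extract_features(cross: np.ndarray, ipsi: np.ndarray, fs: float,
                     grid: WindowGrid, entropy_decimate: int = 2) -> np.ndarray:
    """Extract the 67-feature matrix (n_windows x 67) from the two
    band-passed EEG channels on the given window grid.

    ``entropy_decimate`` subsamples windows before the O(n^2) sample
    entropy; at 250 Hz the default keeps an effective 125 Hz, well above
    the 35 Hz passband edge.
    """
    wc = window_view(cross, fs, grid)
    wi = window_view(ipsi, fs, grid)
    for name, w in (("cross", wc), ("ipsi", wi)):
        bad = ~np.isfinite(w).all(axis=1)
        if bad.any():
            raise FeatureError(
                f"non-finite samples in {name} channel, window index "
                f"{int(np.flatnonzero(bad)[0])}"
            )
    fc, auxc = _channel_features(wc, fs, entropy_decimate)
    fi, auxi = _channel_features(wi, fs, entropy_decimate)

    eps = 1e-12
    relc, reli = auxc["relpow"], auxi["relpow"]
    bpc, bpi = auxc["bandpow"], auxi["bandpow"]
    asym = [
        relc - reli,                                   # antisymmetric
        np.log((bpc + eps) / (bpi + eps)),             # antisymmetric
        (bpc - bpi) / (bpc + bpi + eps),               # antisymmetric
    ]
    asym.append(np.log((auxc["rms"] + eps) / (auxi["rms"] + eps))[:, None])
    asym.append(np.log((auxc["line_length"] + eps)
                       / (auxi["line_length"] + eps))[:, None])
    asym.append((auxc["zc"] - auxi["zc"])[:, None])
    asym.append(_max_xcorr(wc, wi, fs)[:, None])       # symmetric
    X = np.column_stack([fc, fi] + asym)
    assert X.shape[1] == N_FEATURES
    return X


def extract_recording_features(recording, grid: WindowGrid,
                               **kw) -> np.ndarray:
    """Convenience wrapper: pull the two EEG channels off a Recording."""
    from .io import ROLE_EEG_CROSS, ROLE_EEG_IPSI
    cross = recording.get(ROLE_EEG_CROSS)
    ipsi = recording.get(ROLE_EEG_IPSI)
    if cross.fs != ipsi.fs:
        raise ValueError("EEG channels must share a sampling rate")
    return extract_features(cross.samples, ipsi.samples, cross.fs, grid, **kw)
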