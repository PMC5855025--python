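"""Windowed spectro-temporal features of the phasic skin conductance.

The phasic component is segmented into 5 s windows with 4 s overlap
(1 s hop) and each window is summarized by 18 features:

==== ==========================================================
 id   feature
==== ==========================================================
 f1   mean
 f2   population variance
 f3   accumulated GSR (window sum / total task duration)
 f4   maximum value
 f5   power (mean of squared samples)
 f6   number of peaks (second-derivative scan)
 f7   sum of peak amplitudes
 f8   STFT sub-band 1 mean power
 f9   STFT sub-band 2 mean power
 f10  STFT sub-band 3 mean power
 f11  STFT sub-band 4 mean power
 f12  Higuchi fractal dimension
 f13  Katz fractal dimension
 f14  AR coefficient a(1) (Burg, order 5)
 f15  AR coefficient a(2)
 f16  AR coefficient a(3)
 f17  AR coefficient a(4)
 f18  AR coefficient a(5)
==== ==========================================================

A smoothed pseudo Wigner–Ville distribution is provided as a diagnostic
time-frequency map (it is not a feature source beyond f8–f11).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert, spectrogram
from scipy.fft import fft
from statsmodels.regression.linear_model import burg as _burg

FEATURE_NAMES = tuple(f"f{i}" for i in range(1, 19))


@dataclass
class Window:
    """A 5 s phasic-conductance segment with provenance."""

    samples: np.ndarray
    fs: float
    start_s: float = 0.0
    subject_id: str = "s0"
    condition: str = "normal"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


def segment(signal: np.ndarray, fs: float, win_s: float = 5.0,
            overlap_s: float = 4.0, subject_id: str = "s0",
            condition: str = "normal") -> list[Window]:
    """Slice a signal into ``win_s`` windows overlapping by ``overlap_s``.

    The hop is ``win_s - overlap_s`` (1 s by default); a trailing partial
    window is dropped, so a signal of duration T yields
    ``floor((T - win_s)/hop) + 1`` windows.
    """
    if overlap_s >= win_s:
        raise ValueError("overlap must be shorter than the window")
    signal = np.asarray(signal, dtype=float)
    win_n = int(round(win_s * fs))
    hop_n = int(round((win_s - overlap_s) * fs))
    if signal.size < win_n:
        raise ValueError(
            f"signal ({signal.size} samples) shorter than one window ({win_n})")
    out = []
    for start in range(0, signal.size - win_n + 1, hop_n):
        out.append(Window(signal[start:start + win_n], fs,
                          start_s=start / fs, subject_id=subject_id,
                          condition=condition))
    return out


def basic_stats(w: Window, total_task_s: float):
    """f1–f5: mean, variance, accumulated GSR, maximum and power.

    ``accumulated GSR`` divides the window sum by the *total task
    duration* (not the window length), which is what distinguishes it
    from the mean.
    """
    if total_task_s <= 0:
        raise ValueError("total_task_s must be positive")
    x = w.samples
    return (float(np.mean(x)), float(np.var(x)),
            float(np.sum(x) / total_task_s), float(np.max(x)),
            float(np.mean(x ** 2)))


@dataclass
class PeakScan:
    """Second-derivative peak scan of a window.

    ``q0[i] = |P(i+1) - P(i-1)|`` and ``q1[i] = |P(i+2) - 2 P(i) + P(i-2)|``
    are slope and curvature magnitudes; the weighted sum
    ``q2 = 1.3 q0 + 1.1 q1`` is scanned against a threshold, and each
    maximal contiguous run at/above threshold counts as one peak.  The
    run marks the steep rise of a response, so the peak amplitude is the
    maximum sample from the run start through the crest — the end of the
    monotone rise following the run (the scan statistic falls back below
    threshold before the slope reaches zero).

    The arrays cover indices ``2 .. n-3`` of the window (``offset = 2``).
    """

    q0: np.ndarray
    q1: np.ndarray
    q2: np.ndarray
    threshold: float
    peak_regions: list[tuple[int, int]]   # [start, stop) in window indices
    amplitudes: np.ndarray
    offset: int = 2

    @property
    def n_peaks(self) -> int:
        return len(self.peak_regions)

    @property
    def sum_amplitudes(self) -> float:
        return float(np.sum(self.amplitudes))


def detect_peaks(w: Window, threshold: float = 1.0) -> PeakScan:
    """f6/f7 peak scan — see :class:`PeakScan` for the construction."""
    p = w.samples
    if p.size < 5:
        raise ValueError("window must have at least 5 samples")
    # valid range i = 2 .. n-3 so both stride-1 and stride-2 differences exist
    q0 = np.abs(p[3:-1] - p[1:-3])
    q1 = np.abs(p[4:] - 2.0 * p[2:-2] + p[:-4])
    q2 = 1.3 * q0 + 1.1 * q1

    above = q2 >= threshold
    regions, amps = [], []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8),
                                                   [0]))))
    for a, b in zip(edges[::2], edges[1::2]):
        lo, hi = a + 2, b + 2        # back to window indices
        crest = hi
        while crest < p.size and p[crest] >= p[crest - 1]:
            crest += 1
        regions.append((int(lo), int(hi)))
        amps.append(float(np.max(p[lo:crest])))
    return PeakScan(q0, q1, q2, threshold, regions, np.asarray(amps))


def stft_band_features(w: Window, n_bands: int = 4, sub_win_s: float = 1.0,
                       sub_overlap_s: float = 0.5) -> np.ndarray:
    """f8–f11: mean STFT power in equal-width bands spanning [0, fs/2].

    The window is short-time Fourier transformed with ``sub_win_s``
    sub-windows overlapping by ``sub_overlap_s``; the magnitude-squared
    spectra are averaged over time and then over the frequency bins of
    each of the ``n_bands`` equal bands (6.25 Hz wide at fs = 50 Hz).
    """
    nperseg = int(round(sub_win_s * w.fs))
    noverlap = int(round(sub_overlap_s * w.fs))
    if nperseg < 2 or noverlap >= nperseg or w.samples.size < nperseg:
        raise ValueError("degenerate STFT sub-window configuration")
    f, _, sxx = spectrogram(w.samples, fs=w.fs, nperseg=nperseg,
                            noverlap=noverlap, window="hann",
                            detrend=False, mode="psd")
    mean_psd = sxx.mean(axis=1)
    edges = np.linspace(0.0, w.fs / 2, n_bands + 1)
    out = np.empty(n_bands)
    for b in range(n_bands):
        sel = (f >= edges[b]) & ((f < edges[b + 1]) if b < n_bands - 1
                                 else (f <= edges[b + 1]))
        out[b] = mean_psd[sel].mean() if np.any(sel) else 0.0
    return out


def higuchi_fd(samples: np.ndarray, kmax: int = 8) -> float:
    """f12: Higuchi fractal dimension.

    Mean normalized curve length L(k) is computed over decimation steps
    k = 1..kmax and the FD is the slope of log L(k) against log(1/k);
    ~1 for smooth curves, ~2 for white noise.  Invariant to amplitude
    scaling by construction.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n <= 2 * kmax:
        raise ValueError(f"need more than {2 * kmax} samples for kmax={kmax}")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    k_arr = np.arange(1, kmax + 1, dtype=float)
    with np.errstate(divide="ignore"):
        logl = np.log(lk)
    if not np.all(np.isfinite(logl)):   # flat curve: zero length at some k
        return 1.0
    slope, _ = np.polyfit(np.log(1.0 / k_arr), logl, 1)
    return float(slope)


def katz_fd(samples: np.ndarray) -> float:
    """f13: Katz fractal dimension.

    ``D = log10(n) / (log10(n) + log10(d / L))`` with n the number of
    steps, L the total absolute path length and d the maximum absolute
    excursion from the first sample.  A monotone line gives exactly 1;
    a constant series (zero-length path) is defined as 1 with a warning.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    L = float(np.abs(np.diff(x)).sum())
    d = float(np.max(np.abs(x - x[0])))
    if L == 0.0 or d == 0.0:
        warnings.warn("flat window: Katz FD defined as 1.0", RuntimeWarning)
        return 1.0
    n = x.size - 1
    return float(np.log10(n) / (np.log10(n) + np.log10(d / L)))


def ar_coefficients(samples: np.ndarray, order: int = 5) -> np.ndarray:
    """f14–f18: Burg autoregressive coefficients of the demeaned window.

    Convention ``y(n) = sum_k a(k) y(n-k) + e(n)`` — an AR(1) process
    with parameter 0.5 yields ``a(1) ~ +0.5``.  Burg is used (rather
    than Yule–Walker) for its bias behaviour on short windows; an
    all-constant window returns zeros.
    """
    x = np.asarray(samples, dtype=float)
    if order >= x.size:
        raise ValueError("AR order must be smaller than the window length")
    x = x - x.mean()
    if np.allclose(x, 0.0):
        return np.zeros(order)
    coefs, _ = _burg(x, order=order)
    return np.asarray(coefs, dtype=float)


@dataclass
class FeatureVector:
    """The 18 features of one window, plus provenance."""

    values: np.ndarray
    label: str
    subject_id: str
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (18,):
            raise ValueError("a feature vector has exactly 18 entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")

    def as_dict(self) -> dict:
        d = {name: float(v) for name, v in zip(FEATURE_NAMES, self.values)}
        d.update(subject_id=self.subject_id, condition=self.label,
                 window_start_s=self.start_s)
        return d


def extract_features(w: Window, total_task_s: float,
                     peak_threshold: float = 1.0, kmax: int = 8,
                     ar_order: int = 5) -> FeatureVector:
    """Compute the full 18-feature vector for one window."""
    f1, f2, f3, f4, f5 = basic_stats(w, total_task_s)
    scan = detect_peaks(w, threshold=peak_threshold)
    bands = stft_band_features(w)
    fd_h = higuchi_fd(w.samples, kmax=kmax)
    fd_k = katz_fd(w.samples)
    ar = ar_coefficients(w.samples, order=ar_order)
    values = np.concatenate([[f1, f2, f3, f4, f5, scan.n_peaks,
                              scan.sum_amplitudes], bands, [fd_h, fd_k], ar])
    return FeatureVector(values, label=w.condition,
                         subject_id=w.subject_id, start_s=w.start_s)


def extract_table(windows, total_task_s: float, peak_threshold: float = 1.0,
                  kmax: int = 8, ar_order: int = 5):
    """Feature DataFrame for a list of windows.

    A window whose feature computation fails is skipped with a warning,
    never emitted with NaNs.
    """
    import pandas as pd

    rows = []
    for w in windows:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fv = extract_features(w, total_task_s,
                                      peak_threshold=peak_threshold,
                                      kmax=kmax, ar_order=ar_order)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"window at {w.start_s:.1f}s "
                          f"({w.subject_id}/{w.condition}) skipped: {exc}")
            continue
        rows.append(fv.as_dict())
    return pd.DataFrame(rows)


@dataclass
class TFMap:
    """Time × normalized-frequency power map (diagnostic)."""

    matrix: np.ndarray      # shape (n_times, n_freqs)
    time_axis: np.ndarray   # seconds
    freq_axis: np.ndarray   # normalized frequency, 0–1 == 0–fs/2

    def total_energy(self) -> float:
        return float(self.matrix.sum())


def wvd_spectrogram(signal: np.ndarray, fs: float, nfft: int = 256,
                    lag_window_s: float = 2.0,
                    time_smooth_s: float = 0.2) -> TFMap:
    """Smoothed pseudo Wigner–Ville distribution of the analytic signal.

    The instantaneous autocorrelation ``z[n+m] z*[n-m]`` is windowed in
    lag (Hamming, ``lag_window_s``) to attenuate cross-terms in
    frequency, Fourier transformed over the lag, and smoothed along time
    (normalized Hamming, ``time_smooth_s``) to attenuate cross-terms in
    time.  Normalization: the map sums to the analytic-signal energy
    ``sum |z[n]|^2`` (exactly before time smoothing, which is
    sum-preserving away from the edges).

    A pure tone at f0 produces a ridge at normalized frequency
    ``2 f0 / fs``.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 64:
        raise ValueError("signal too short for a WVD (need >= 64 samples)")
    n = x.size
    z = hilbert(x)
    max_lag = min(nfft // 2, max(2, int(round(lag_window_s * fs / 2))))
    ham = np.hamming(2 * max_lag - 1)
    h = ham[max_lag - 1:] / ham[max_lag - 1]   # half window, h[0] == 1

    acf = np.zeros((nfft, n), dtype=complex)
    acf[0] = np.abs(z) ** 2
    for m in range(1, max_lag):
        prod = np.zeros(n, dtype=complex)
        prod[m:n - m] = z[2 * m:] * np.conj(z[:n - 2 * m])
        acf[m] = h[m] * prod
        acf[nfft - m] = np.conj(acf[m])
    W = np.real(fft(acf, axis=0)) / nfft

    g_len = max(1, int(round(time_smooth_s * fs)) | 1)
    if g_len > 1:
        from scipy.ndimage import convolve1d

        g = np.hamming(g_len)
        W = convolve1d(W, g / g.sum(), axis=1, mode="nearest")

    return TFMap(matrix=W.T, time_axis=np.arange(n) / fs,
                 freq_axis=np.arange(nfft) / nfft)
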