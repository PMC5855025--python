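"""Raw-GSR preprocessing: low-pass filtering and resampling to 50 Hz.

Motion, hand/finger EMG and other high-frequency artifacts contaminate
wrist-worn GSR; a 10th-order Butterworth low-pass below 20 Hz removes
them, after which the signal is resampled to the 50 Hz working rate used
by the decomposition and feature stages (giving a 0–25 Hz analysis band).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt

from .recording import GSRRecording


def lowpass_filter(rec: GSRRecording, cutoff: float = 20.0,
                   order: int = 10) -> GSRRecording:
    """Zero-phase Butterworth low-pass.

    The filter is applied forward and backward (``sosfiltfilt``) so SCR
    onset latencies are not delayed, and is realized as second-order
    sections for numerical stability at order 10.
    """
    if cutoff >= rec.fs / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below Nyquist {rec.fs / 2} Hz")
    sos = butter(order, cutoff, btype="lowpass", fs=rec.fs, output="sos")
    # sosfiltfilt needs > 3 * (2 * n_sections + 1) samples of warm-up
    padlen = 3 * (2 * sos.shape[0] + 1)
    if rec.samples.size <= padlen:
        raise ValueError(
            f"signal too short for order-{order} zero-phase filtering "
            f"(need > {padlen} samples, got {rec.samples.size})")
    return rec.with_samples(sosfiltfilt(sos, rec.samples))


def resample_to(rec: GSRRecording, fs_out: float = 50.0) -> GSRRecording:
    """Resample to ``fs_out`` by a polyphase rational-rate filter.

    The up/down ratio is the rational approximation of
    ``fs_out / fs_in`` (denominator <= 1000); non-integer ratios are
    handled by the same polyphase path, never by silent truncation.
    Line-extension padding keeps constant signals exactly constant at
    the edges.  Anti-aliasing for downsampling is doubly guaranteed: the
    polyphase filter itself plus the prior <20 Hz low-pass.
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_out == rec.fs:
        return rec
    frac = Fraction(fs_out / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = resample_poly(rec.samples, up, down, padtype="line")
    return rec.with_samples(out, fs=fs_out)


def preprocess(rec: GSRRecording, cutoff: float = 20.0, order: int = 10,
               fs_out: float = 50.0) -> GSRRecording:
    """Standard chain: low-pass filter then resample to the working rate."""
    return resample_to(lowpass_filter(rec, cutoff, order), fs_out)
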