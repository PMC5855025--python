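"""Synthetic galvanic-skin-response generator with known ground truth.

Emulates the kind of data a wrist-worn EDA sensor records during short
(~2 min) driving tasks: a slowly drifting tonic conductance level with
superposed skin conductance responses (SCRs).  Each SCR is a sudomotor
impulse convolved with a biexponential (Bateman) impulse response, and
distracted conditions (phone conversation, texting) fire impulses — and
bursts of impulses — at a higher rate than attentive driving.  Because the
impulse train, tonic level and phasic component are all retained as ground
truth, every downstream stage (filtering, deconvolution, feature
extraction, classification) can be validated quantitatively.

Units: conductance in microsiemens (µS); the driver (sudomotor activity)
in µS/s, so that convolution with the unit-area impulse response —
``numpy``-convolution divided by the sampling rate — returns µS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .cda import bateman_kernel
from .recording import CONDITIONS, GSRRecording


@dataclass(frozen=True)
class ConditionProfile:
    """Statistical profile of sudomotor activity under one driving condition.

    Parameters
    ----------
    name : str
        Condition label, one of ``normal``, ``phone``, ``text``.
    impulse_rate : float
        Mean rate of primary SCR impulses (per second, Poisson).
    burst_prob : float
        Probability that a primary impulse spawns a burst: 1–3 extra
        impulses trailing it at 0.5–1.5 s spacing, producing the
        overlapping-SCR regime that deconvolution exists to untangle.
    amp_shape, amp_scale : float
        Gamma distribution parameters of the impulse amplitude
        (time-area of the driver spike, µS·s/s = µS).
    """

    name: str
    impulse_rate: float
    burst_prob: float
    amp_shape: float = 2.0
    amp_scale: float = 0.3

    def __post_init__(self) -> None:
        if self.impulse_rate < 0:
            raise ValueError("impulse_rate must be >= 0")
        if not 0.0 <= self.burst_prob <= 1.0:
            raise ValueError("burst_prob must lie in [0, 1]")


#: Default condition profiles.  Distraction raises both the impulse rate and
#: the tendency to fire bursts, mirroring the denser phasic activity seen
#: under cognitive (phone) and cognitive+visual (text) load.
DEFAULT_PROFILES: dict[str, ConditionProfile] = {
    "normal": ConditionProfile("normal", impulse_rate=0.05, burst_prob=0.1),
    "phone": ConditionProfile("phone", impulse_rate=0.25, burst_prob=0.4),
    "text": ConditionProfile("text", impulse_rate=0.35, burst_prob=0.5),
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic recording.

    ``tau1``/``tau2`` are the rise/decay time constants of the Bateman
    impulse response; ``tonic_base`` and ``tonic_drift_sd`` set the tonic
    level and its slow drift; ``noise_sd`` is additive white measurement
    noise on the conductance; ``artifact_sd`` > 0 adds band-limited
    (>20 Hz) EMG-like artifact bursts, used only to exercise the
    preprocessing filter.
    """

    fs_raw: float = 200.0
    duration_s: float = 120.0
    tau1: float = 1.0
    tau2: float = 3.75
    tonic_base: float = 4.0
    tonic_drift_sd: float = 0.15
    noise_sd: float = 0.01
    artifact_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0 < self.tau1 < self.tau2:
            raise ValueError("need 0 < tau1 < tau2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Simulated truth kept alongside a synthetic recording."""

    impulse_times: np.ndarray   # SCR onset times (s)
    impulse_amps: np.ndarray    # driver spike areas (µS)
    tonic_truth: np.ndarray     # tonic conductance (µS)
    phasic_truth: np.ndarray    # phasic conductance driver*IRF (µS)
    driver_truth: np.ndarray    # impulse-train driver series (µS/s)

    def __post_init__(self) -> None:
        if len(self.impulse_times) != len(self.impulse_amps):
            raise ValueError("impulse_times and impulse_amps must align")


def generate_phasic_driver(profile: ConditionProfile, duration_s: float,
                           fs: float, seed: int):
    """Draw a sudomotor impulse train for one condition.

    Primary impulses arrive as a Poisson process at ``profile.impulse_rate``;
    with probability ``burst_prob`` a primary impulse trails 1–3 extra
    impulses at 0.5–1.5 s spacing.  Amplitudes are Gamma distributed.

    Returns
    -------
    driver : ndarray
        Sparse spike series (µS/s) of length ``round(duration_s * fs)``;
        a spike of area ``a`` is a single sample of height ``a * fs``.
    times, amps : ndarray
        Impulse onset times (s) and areas (µS), sorted by time.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))

    n_primary = rng.poisson(profile.impulse_rate * duration_s)
    times = list(rng.uniform(0.0, duration_s, size=n_primary))
    primary = sorted(times)
    for t0 in primary:
        if rng.uniform() < profile.burst_prob:
            t = t0
            for _ in range(rng.integers(1, 4)):
                t = t + rng.uniform(0.5, 1.5)
                if t < duration_s:
                    times.append(t)
    times = np.sort(np.asarray(times, dtype=float))
    amps = rng.gamma(profile.amp_shape, profile.amp_scale, size=times.size)

    driver = np.zeros(n)
    idx = np.minimum(np.round(times * fs).astype(int), n - 1)
    np.add.at(driver, idx, amps * fs)
    return driver, times, amps


def generate_tonic(duration_s: float, fs: float, base: float,
                   drift_sd: float, seed: int, n_components: int = 6,
                   max_freq_hz: float = 0.02) -> np.ndarray:
    """Generate a strictly positive, slowly drifting tonic level.

    The drift is a sum of ``n_components`` sinusoids with random
    frequencies below ``max_freq_hz`` (well under 0.05 Hz), random phases,
    and equal amplitudes chosen so that the drift RMS equals ``drift_sd``.
    Being a finite sum of sub-0.05 Hz sinusoids, the series has no
    spectral energy above 0.05 Hz by construction.
    """
    if base <= 0:
        raise ValueError("tonic base level must be positive")
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    series = np.full(t.size, float(base))
    if drift_sd > 0:
        amp = drift_sd * np.sqrt(2.0 / n_components)
        freqs = rng.uniform(0.002, max_freq_hz, size=n_components)
        phases = rng.uniform(0, 2 * np.pi, size=n_components)
        for f, ph in zip(freqs, phases):
            series += amp * np.sin(2 * np.pi * f * t + ph)
    lo = series.min()
    if lo <= 0:  # large drift_sd relative to base: shift, keep it positive
        series += 0.01 * base - lo
    return series


def apply_irf(driver: np.ndarray, kernel: np.ndarray, fs: float) -> np.ndarray:
    """Causal convolution of a driver (µS/s) with the IRF, returning µS."""
    out = fftconvolve(driver, kernel)[: driver.size] / fs
    return out


def synthesize_recording(config: SynthConfig, profile: ConditionProfile,
                         subject_id: str = "s0"):
    """Build one synthetic recording: tonic + driver*IRF + noise.

    Returns ``(GSRRecording, GroundTruth)``.  Deterministic for a fixed
    ``(config, profile)`` pair — all randomness derives from
    ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(4)
    fs = config.fs_raw
    driver, times, amps = generate_phasic_driver(
        profile, config.duration_s, fs, seed=seeds[0])
    tonic = generate_tonic(config.duration_s, fs, config.tonic_base,
                           config.tonic_drift_sd, seed=seeds[1])
    kernel = bateman_kernel(config.tau1, config.tau2, fs)
    phasic = np.maximum(apply_irf(driver, kernel, fs), 0.0)  # clip FFT dust

    rng = np.random.default_rng(seeds[2])
    sc = tonic + phasic
    if config.noise_sd > 0:
        sc = sc + rng.normal(0.0, config.noise_sd, size=sc.size)
    if config.artifact_sd > 0:
        sc = sc + _emg_artifact(sc.size, fs, config.artifact_sd, seeds[3])

    rec = GSRRecording(sc, fs=fs, subject_id=subject_id,
                       condition=profile.name)
    truth = GroundTruth(times, amps, tonic, phasic, driver)
    return rec, truth


def _emg_artifact(n: int, fs: float, sd: float, seed: int) -> np.ndarray:
    """Band-limited (>20 Hz) noise bursts emulating EMG contamination."""
    from scipy.signal import butter, sosfilt

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd, size=n)
    sos = butter(4, 20.0, btype="highpass", fs=fs, output="sos")
    noise = sosfilt(sos, noise)
    envelope = np.zeros(n)
    for _ in range(rng.integers(3, 7)):  # a handful of ~0.5 s bursts
        start = rng.integers(0, max(1, n - int(0.5 * fs)))
        envelope[start:start + int(0.5 * fs)] = 1.0
    return noise * envelope


def generate_cohort(n_subjects: int, config: SynthConfig,
                    profiles: dict[str, ConditionProfile] | None = None):
    """Simulate a cohort: each subject records once per condition.

    Per-subject variability: the tonic base is drawn Uniform(2, 8) µS and
    all condition impulse rates are scaled by a common Uniform(0.8, 1.2)
    factor, so the normal < phone < text rate ordering is preserved
    within every subject while levels differ across subjects.

    Returns a list of ``(GSRRecording, GroundTruth)`` of length
    ``3 * n_subjects``, ordered subject-major.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    profiles = dict(DEFAULT_PROFILES if profiles is None else profiles)
    master = np.random.SeedSequence(config.seed)
    out = []
    for s, child in enumerate(master.spawn(n_subjects)):
        state = child.generate_state(2 + len(profiles))
        subj_rng = np.random.default_rng(state[0])
        base = subj_rng.uniform(2.0, 8.0)
        rate_scale = subj_rng.uniform(0.8, 1.2)
        for c, cond in enumerate(CONDITIONS):
            prof = profiles[cond]
            prof_s = ConditionProfile(prof.name,
                                      prof.impulse_rate * rate_scale,
                                      prof.burst_prob,
                                      prof.amp_shape, prof.amp_scale)
            cfg_s = SynthConfig(
                fs_raw=config.fs_raw, duration_s=config.duration_s,
                tau1=config.tau1, tau2=config.tau2,
                tonic_base=base, tonic_drift_sd=config.tonic_drift_sd,
                noise_sd=config.noise_sd, artifact_sd=config.artifact_sd,
                seed=int(state[1 + c]) % (2**31),
            )
            rec, truth = synthesize_recording(cfg_s, prof_s,
                                              subject_id=f"s{s:02d}")
            out.append((rec, truth))
    return out


def write_cohort(cohort, out_dir) -> Path:
    """Write a cohort to disk: one signal CSV and one ground-truth pair
    (JSON impulses + CSV series) per recording, plus a manifest JSON.

    Returns the manifest path.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec, truth in cohort:
        stem = f"{rec.subject_id}_{rec.condition}"
        sig = out_dir / f"{stem}.csv"
        rec.to_csv(sig)
        gt_json = out_dir / f"{stem}_truth.json"
        gt_json.write_text(json.dumps({
            "impulse_times_s": [round(float(x), 6) for x in truth.impulse_times],
            "impulse_amps_uS": [round(float(x), 6) for x in truth.impulse_amps],
        }, indent=1))
        gt_csv = out_dir / f"{stem}_truth.csv"
        pd.DataFrame({"tonic_truth_uS": truth.tonic_truth,
                      "phasic_truth_uS": truth.phasic_truth}).to_csv(
            gt_csv, index=False)
        manifest.append({"subject": rec.subject_id, "condition": rec.condition,
                         "fs": rec.fs, "signal": sig.name,
                         "truth_json": gt_json.name, "truth_csv": gt_csv.name})
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath
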