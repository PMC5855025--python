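"""Containers and CSV I/O for single-channel skin-conductance recordings.

A recording is a uniformly sampled galvanic skin response (GSR, also called
skin conductance / electrodermal activity) trace in microsiemens, tagged with
the subject it came from and the driving condition under which it was
recorded (``normal``, ``phone`` or ``text``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONDITIONS = ("normal", "phone", "text")


@dataclass
class GSRRecording:
    """A single skin-conductance recording.

    Parameters
    ----------
    samples : ndarray
        Conductance samples in microsiemens (µS).
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Subject identifier.
    condition : str
        One of ``normal``, ``phone``, ``text``.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = "s0"
    condition: str = "normal"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "GSRRecording":
        return replace(self, samples=np.asarray(samples, float),
                       fs=self.fs if fs is None else fs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "eda_uS": self.samples})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_recording_csv(path, subject_id: str = "s0",
                       condition: str = "normal") -> GSRRecording:
    """Read a ``time_s,eda_uS`` CSV written by :meth:`GSRRecording.to_csv`.

    The sampling rate is inferred from the median time step.
    """
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = float(np.median(np.diff(t)))
    return GSRRecording(df["eda_uS"].to_numpy(), fs=1.0 / dt,
                        subject_id=subject_id, condition=condition)
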