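"""Filtering and epoching of EEG recordings.

Filters are zero-phase (forward-backward) so event-related waveforms keep
their latencies: a 4th-order Butterworth band-pass for the analysis band
and an IIR notch for mains interference.  Epoching cuts the recording into
equal-length windows; an amplitude-threshold rule rejects windows
contaminated by blink/movement artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .eeg_io import EEGRecording

__all__ = ["Epoch", "bandpass", "notch", "epoch_signal", "reject_artifacts"]


@dataclass(frozen=True)
class Epoch:
    """A fixed-length window cut from a parent recording."""

    samples: np.ndarray
    subject_id: str
    phase: str
    start: int  # sample index in the parent recording

    def __len__(self) -> int:
        return self.samples.size


def bandpass(rec: EEGRecording, low: float = 0.5, high: float = 60.0,
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass; length and metadata preserved."""
    nyq = rec.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2, got ({low}, {high}) at fs={rec.fs}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    # even-extension padding sized to the slow low-frequency corner: the
    # default odd extension rings the 0.5 Hz pole across short recordings
    padlen = min(rec.n_samples - 1, int(round(3.0 * rec.fs / low)))
    filtered = sps.sosfiltfilt(sos, rec.samples, padtype="even", padlen=padlen)
    return rec.copy_with(samples=filtered)


def notch(rec: EEGRecording, line_freq: float = 60.0, q: float = 30.0) -> EEGRecording:
    """Zero-phase narrow-band rejection at the mains frequency.

    Default 60 Hz; pass ``line_freq=50`` for 50 Hz mains.
    """
    if not 0 < line_freq < rec.fs / 2.0:
        raise ValueError(f"line_freq must lie in (0, fs/2), got {line_freq}")
    b, a = sps.iirnotch(line_freq, q, fs=rec.fs)
    filtered = sps.filtfilt(b, a, rec.samples)
    return rec.copy_with(samples=filtered)


def epoch_signal(rec: EEGRecording, window_s: float = 4.0,
                 overlap: float = 0.0) -> list[Epoch]:
    """Cut a recording into equal-length windows.

    Yields ``floor((N - w) / step) + 1`` epochs with ``w = window_s * fs``
    and ``step = w * (1 - overlap)``; a trailing partial window is dropped.
    A window longer than the recording gives an empty list with a warning.
    """
    w = int(round(window_s * rec.fs))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    n = rec.n_samples
    if w > n:
        warnings.warn(
            f"window of {w} samples exceeds recording length {n}; no epochs",
            stacklevel=2,
        )
        return []
    step = max(1, int(round(w * (1.0 - overlap))))
    starts = range(0, n - w + 1, step)
    return [
        Epoch(samples=rec.samples[s:s + w].copy(), subject_id=rec.subject_id,
              phase=rec.phase, start=s)
        for s in starts
    ]


def reject_artifacts(epochs: list[Epoch], threshold_uv: float = 100.0) -> list[Epoch]:
    """Drop epochs whose absolute amplitude exceeds *threshold_uv*."""
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    return [e for e in epochs if np.max(np.abs(e.samples)) <= threshold_uv]
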