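"""Welch power-spectral-density estimation and EEG band decomposition.

The PSD is estimated by Welch's averaged-periodogram method (overlapping
Hann-windowed segments, default 2 s at 50% overlap, giving 0.5 Hz
resolution at 512 samples/s).  Band powers integrate the PSD over the five
canonical rhythms — delta (0.5-4 Hz), theta (4-8), alpha (8-12), beta
(12-30), gamma (30-60) — with relative powers expressed as fractions of
the broadband (0.5-60 Hz) power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .eeg_io import EEGRecording
from .synthetic import BANDS, BROADBAND

__all__ = ["PSD", "BandPowers", "welch_psd", "band_powers", "nyquist_min_fs"]


@dataclass(frozen=True)
class PSD:
    """One-sided power spectral density on a frequency grid.

    ``power`` is in µV²/Hz; integrating it over frequency recovers signal
    variance (within window bias).
    """

    freqs: np.ndarray
    power: np.ndarray
    window: str
    segment_s: float
    overlap: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")


@dataclass(frozen=True)
class BandPowers:
    """Absolute (µV²) and relative band powers per EEG rhythm."""

    absolute: dict[str, float]
    relative: dict[str, float]
    broadband: float

    def dominant_band(self) -> str:
        """Name of the rhythm carrying the largest relative power."""
        return max(self.relative, key=self.relative.get)


def welch_psd(rec: EEGRecording, segment_s: float = 2.0, overlap: float = 0.5,
              window: str = "hann") -> PSD:
    """Welch PSD of a recording.

    Raises if the recording is shorter than one segment; shorten
    ``segment_s`` in that case.
    """
    nperseg = int(round(segment_s * rec.fs))
    if nperseg > rec.n_samples:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{segment_s} s segment; use a smaller segment_s"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    freqs, power = sps.welch(
        rec.samples, fs=rec.fs, window=window, nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
    )
    return PSD(freqs=freqs, power=power, window=window,
               segment_s=segment_s, overlap=overlap)


def _integrate(freqs: np.ndarray, power: np.ndarray,
               low: float, high: float) -> float:
    """Trapezoidal integral of the PSD over [low, high].

    The grid is augmented with the exact band edges (linear interpolation)
    so adjacent bands tile the broadband range without gap or overlap and
    their powers sum exactly to the broadband power.
    """
    grid = np.union1d(freqs, [low, high])
    grid = grid[(grid >= low) & (grid <= high)]
    vals = np.interp(grid, freqs, power)
    return float(np.trapezoid(vals, grid))


def band_powers(psd: PSD) -> BandPowers:
    """Decompose a PSD into absolute and relative rhythm-band powers."""
    if psd.freqs[-1] < BROADBAND[1]:
        raise ValueError(
            f"PSD must cover up to {BROADBAND[1]} Hz, reaches only {psd.freqs[-1]:g} Hz"
        )
    absolute = {
        name: _integrate(psd.freqs, psd.power, low, high)
        for name, (low, high) in BANDS.items()
    }
    broadband = sum(absolute.values())
    if broadband > 0:
        relative = {name: p / broadband for name, p in absolute.items()}
    else:
        relative = {name: 0.0 for name in absolute}
    return BandPowers(absolute=absolute, relative=relative, broadband=broadband)


def nyquist_min_fs(fmax: float) -> float:
    """Minimum sampling rate (Hz) that avoids aliasing content up to *fmax*.

    The sampling theorem requires fs >= 2 * fmax; for EEG limited to 60 Hz
    this gives 120 samples/s.
    """
    if fmax < 0:
        raise ValueError("fmax must be non-negative")
    return 2.0 * fmax
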