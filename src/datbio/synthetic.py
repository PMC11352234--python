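"""Synthetic single-channel EEG with controlled band structure.

No public recordings exist for the therapy protocol this package analyses
(about 60 s at rest, 5 min of therapy, 60 s of rest again, one frontopolar
channel at 512 samples/s), so this module fabricates cohorts with the same
shape: a 1/f ("pink") background, band-limited activity in the five
canonical EEG rhythms, additive white noise, and a poor-signal quality
series emulating sensor stabilization.

Each band component is Gaussian white noise band-pass filtered to its
rhythm's range and rescaled to a requested RMS amplitude; an optional
pure-sinusoid mode places a single tone at the band's center frequency,
which is convenient for analytic tests.  The generator is fully
deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .eeg_io import EEGRecording, PHASES

__all__ = ["BandProfile", "CohortSpec", "generate_recording", "generate_cohort",
           "BANDS", "rest_profile", "therapy_profile"]

#: canonical EEG rhythm ranges in Hz (delta, theta, alpha, beta, gamma)
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 60.0),
}

BROADBAND = (0.5, 60.0)


@dataclass(frozen=True)
class BandProfile:
    """RMS amplitude (µV) per EEG rhythm plus background terms.

    ``pink_exponent`` sets the slope of the 1/f^exponent background and
    ``pink_amplitude`` its RMS in µV; ``noise_sd`` is additive white
    measurement noise.  ``sinusoid`` switches band components from filtered
    noise to pure tones at band centers.
    """

    delta: float = 0.0
    theta: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    pink_exponent: float = 1.0
    pink_amplitude: float = 0.0
    noise_sd: float = 0.0
    sinusoid: bool = False

    def __post_init__(self) -> None:
        for name in (*BANDS, "pink_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def band_amplitudes(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in BANDS}


def rest_profile() -> BandProfile:
    """Default resting-state profile: alpha-dominant over a 1/f background."""
    return BandProfile(delta=4.0, theta=3.0, alpha=6.0, beta=2.0, gamma=1.0,
                       pink_amplitude=3.0, noise_sd=1.0)


def therapy_profile() -> BandProfile:
    """Default during-therapy profile.

    There is no published quantitative account of how the therapy shifts
    band powers; this placeholder boosts beta/gamma and suppresses alpha,
    i.e. a shift toward faster rhythms under external stimulation.
    """
    return BandProfile(delta=3.0, theta=3.0, alpha=2.0, beta=6.0, gamma=4.0,
                       pink_amplitude=3.0, noise_sd=1.0)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort.

    One recording per phase per subject: ``before`` and ``after`` drawn
    from ``rest``, ``during`` drawn from ``therapy``.  Durations default to
    the study protocol (60 s rest, 300 s therapy, 60 s rest) at 512
    samples/s.
    """

    n_subjects: int = 4
    durations_s: tuple[float, float, float] = (60.0, 300.0, 60.0)
    fs: float = 512.0
    rest: BandProfile = field(default_factory=rest_profile)
    therapy: BandProfile = field(default_factory=therapy_profile)
    seed: int = 0
    stabilization_s: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(d <= 0 for d in self.durations_s):
            raise ValueError("durations must be positive")
        if self.fs < 120:
            raise ValueError("fs must be at least 120 Hz (Nyquist for 60 Hz)")
        if self.rest == self.therapy:
            raise ValueError("rest and therapy profiles must differ")


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with power spectrum proportional to 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to *band*."""
    low, high = band
    high = min(high, 0.499 * fs)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_recording(profile: BandProfile, duration_s: float, fs: float = 512.0,
                       phase: str = "before", seed: int = 0,
                       subject_id: str = "S01",
                       stabilization_s: float = 0.5) -> EEGRecording:
    """Synthesize one EEG recording from a band profile.

    The returned recording carries a poor-signal series that reads 200 for
    the first ``stabilization_s`` seconds and 0 afterwards, emulating the
    sensor settling after electrode contact.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs < 120:
        raise ValueError("fs must be at least 120 Hz")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    for name, (low, high) in BANDS.items():
        amp = getattr(profile, name)
        if amp == 0:
            # keep the stream position deterministic regardless of amplitudes
            rng.standard_normal(n) if not profile.sinusoid else None
            continue
        if profile.sinusoid:
            f0 = 0.5 * (low + high)
            phi = 0.0
            x = x + amp * np.sqrt(2.0) * np.sin(2 * np.pi * f0 * np.arange(n) / fs + phi)
        else:
            x = x + amp * _band_noise(n, fs, (low, high), rng)
    if profile.pink_amplitude > 0:
        x = x + profile.pink_amplitude * _pink_noise(n, profile.pink_exponent, rng)
    if profile.noise_sd > 0:
        x = x + profile.noise_sd * rng.standard_normal(n)
    n_stab = min(n, int(round(stabilization_s * fs)))
    poor = np.zeros(n, dtype=int)
    poor[:n_stab] = 200
    return EEGRecording(samples=x, fs=fs, phase=phase, subject_id=subject_id,
                        poor_signal=poor)


def subject_seed(master_seed: int, subject_index: int, phase_index: int) -> int:
    """Deterministic sub-seed for subject *i*, phase *p*.

    ``master_seed + 1000*i + p`` — documented so any single recording of a
    cohort can be regenerated in isolation.
    """
    return int(master_seed) + 1000 * int(subject_index) + int(phase_index)


def generate_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """Generate ``3 × n_subjects`` recordings (before/during/after each).

    Before/after phases use the rest profile, the during phase the therapy
    profile.  Per-recording seeds derive reproducibly from the master seed
    via :func:`subject_seed`.
    """
    recordings: list[EEGRecording] = []
    for i in range(spec.n_subjects):
        sid = f"S{i + 1:02d}"
        for p, phase in enumerate(PHASES):
            profile = spec.therapy if phase == "during" else spec.rest
            recordings.append(generate_recording(
                profile,
                duration_s=spec.durations_s[p],
                fs=spec.fs,
                phase=phase,
                seed=subject_seed(spec.seed, i, p),
                subject_id=sid,
                stabilization_s=spec.stabilization_s,
            ))
    return recordings
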