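"""Event-related averaging and self-affine fluctuation analysis.

The self-affine analysis (SAA) here is a root-mean-square fluctuation
analysis of the signal's cumulative profile: integrate the mean-removed
signal, split the profile into windows of length ``s`` for a log-spaced
set of scales, linearly detrend each window and take the RMS of the
residuals.  On a log-log plot the resulting fluctuation function F(s) of
uncorrelated noise has slope 1/2 (the Hurst exponent of a random walk
profile); correlated signals bend the curve, and the points where it
crosses a reference line — its own least-squares fit by default, or the
zero line — are the "crossovers" summarized per therapy phase.

Two crossover statistics compare the phases of one session:

* ``S_BA = |C_A - C_B|`` — absolute distance between the before- and
  after-therapy crossovers (rest-to-rest similarity; small = similar);
* ``S_DR = (|C_A - C_D| + |C_D - C_B|) / 2`` — mean absolute distance of
  the during-therapy crossover to the two rest crossovers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Epoch

__all__ = [
    "SAACurve", "CrossoverSummary", "erp_average", "saa_curve",
    "detect_crossover", "similarity_before_after", "similarity_during",
    "crossover_summary",
]


@dataclass(frozen=True)
class SAACurve:
    """A fluctuation curve in log-log coordinates with its reference line.

    ``log_scales`` and ``log_fluct`` are log10 of window length and RMS
    fluctuation; ``slope``/``intercept`` define the least-squares reference
    line.  ``degenerate`` marks curves from (near-)constant signals whose
    fluctuations vanish.
    """

    log_scales: np.ndarray
    log_fluct: np.ndarray
    slope: float
    intercept: float
    degenerate: bool = False

    def reference(self) -> np.ndarray:
        """Reference-line ordinates on the curve's abscissa grid."""
        return self.slope * self.log_scales + self.intercept

    def residuals(self) -> np.ndarray:
        return self.log_fluct - self.reference()


@dataclass(frozen=True)
class CrossoverSummary:
    """Per-phase crossover indices and the two similarity statistics."""

    C_B: int
    C_D: int
    C_A: int
    S_BA: float
    S_DR: float


def erp_average(epochs: list[Epoch] | list[np.ndarray]) -> np.ndarray:
    """Pointwise mean waveform across equal-length epochs.

    Event-related potentials are averages of responses time-locked to an
    event; here the "event" is whatever epoching the caller applied.
    """
    if len(epochs) == 0:
        raise ValueError("need at least one epoch")
    arrays = [e.samples if isinstance(e, Epoch) else np.asarray(e, dtype=float)
              for e in epochs]
    lengths = {a.size for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"epochs have unequal lengths: {sorted(lengths)}")
    return np.mean(arrays, axis=0)


def _rms_fluctuation(profile: np.ndarray, scale: int) -> float:
    """RMS of linearly detrended windows of length *scale* of the profile."""
    n_win = profile.size // scale
    segments = profile[: n_win * scale].reshape(n_win, scale)
    t = np.arange(scale, dtype=float)
    # least-squares line per window, vectorized over windows
    t_mean = t.mean()
    y_mean = segments.mean(axis=1, keepdims=True)
    denom = np.sum((t - t_mean) ** 2)
    slope = (segments - y_mean) @ (t - t_mean) / denom
    resid = segments - y_mean - slope[:, None] * (t - t_mean)
    return float(np.sqrt(np.mean(resid**2)))


def saa_curve(x: np.ndarray, n_scales: int = 32, min_scale: int = 4) -> SAACurve:
    """Fluctuation curve of the cumulative profile of *x*.

    Scales are log-spaced between ``min_scale`` and ``len(x) // 4``.  A
    constant (or otherwise fluctuation-free) signal yields a curve flagged
    ``degenerate`` rather than an error.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4 * min_scale:
        raise ValueError(f"signal of {x.size} samples is too short for SAA")
    profile = np.cumsum(x - x.mean())
    max_scale = x.size // 4
    scales = np.unique(np.round(
        np.geomspace(min_scale, max_scale, n_scales)).astype(int))
    fluct = np.array([_rms_fluctuation(profile, s) for s in scales])
    if np.any(fluct <= 0):
        return SAACurve(log_scales=np.log10(scales.astype(float)),
                        log_fluct=np.full(scales.size, -np.inf),
                        slope=0.0, intercept=0.0, degenerate=True)
    log_s = np.log10(scales.astype(float))
    log_f = np.log10(fluct)
    slope, intercept = np.polyfit(log_s, log_f, 1)
    return SAACurve(log_scales=log_s, log_fluct=log_f,
                    slope=float(slope), intercept=float(intercept))


def detect_crossover(curve: SAACurve, mode: str = "first_crossing",
                     reference: str = "fitted") -> tuple[int, bool]:
    """Crossover of a fluctuation curve against a reference line.

    ``reference`` is the curve's own least-squares line (``"fitted"``) or
    the zero line (``"zero"``).  ``mode="first_crossing"`` returns the
    smallest abscissa index where the residual changes sign;
    ``mode="crossing_count"`` returns the number of sign changes.  The
    second element of the result is True when at least one crossing
    exists; with no crossing the index is 0 and the flag False.
    """
    if curve.degenerate:
        raise ValueError("cannot detect crossover on a degenerate curve")
    if reference == "fitted":
        resid = curve.residuals()
    elif reference == "zero":
        resid = curve.log_fluct
    else:
        raise ValueError(f"unknown reference {reference!r}")
    signs = np.sign(resid)
    # carry the last nonzero sign through exact zeros
    last = 0.0
    carried = np.empty_like(signs)
    for i, s in enumerate(signs):
        if s != 0:
            last = s
        carried[i] = last
    changes = np.nonzero((carried[1:] != carried[:-1])
                         & (carried[1:] != 0) & (carried[:-1] != 0))[0]
    if mode == "first_crossing":
        if changes.size == 0:
            return 0, False
        return int(changes[0] + 1), True
    if mode == "crossing_count":
        return int(changes.size), changes.size > 0
    raise ValueError(f"unknown mode {mode!r}")


def similarity_before_after(C_B: float, C_A: float) -> float:
    """Rest-to-rest crossover similarity ``S_BA = |C_A - C_B|``."""
    if C_B < 0 or C_A < 0:
        raise ValueError("crossover indices must be non-negative")
    return float(abs(C_A - C_B))


def similarity_during(C_B: float, C_D: float, C_A: float) -> float:
    """Therapy-phase crossover similarity.

    ``S_DR = (|C_A - C_D| + |C_D - C_B|) / 2`` — how far the
    during-therapy crossover sits from the two resting crossovers.
    """
    if min(C_B, C_D, C_A) < 0:
        raise ValueError("crossover indices must be non-negative")
    return float((abs(C_A - C_D) + abs(C_D - C_B)) / 2.0)


def crossover_summary(C_B: int, C_D: int, C_A: int) -> CrossoverSummary:
    """Bundle the three phase crossovers with both similarity statistics."""
    return CrossoverSummary(
        C_B=C_B, C_D=C_D, C_A=C_A,
        S_BA=similarity_before_after(C_B, C_A),
        S_DR=similarity_during(C_B, C_D, C_A),
    )
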