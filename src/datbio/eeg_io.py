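"""Reading and writing single-channel EEG recordings.

The consumer-grade acquisition this package targets produces one voltage
series per recording (frontopolar electrode, 512 samples/s) together with a
0-255 "poor signal" quality flag; a recording is considered stabilized once
that flag first drops to 51 or below.  Two on-disk formats are supported:

* a plain-text CSV dialect (lossless, the canonical interchange format):
  ``#``-prefixed header lines carrying metadata, then one ``uV`` column and
  an optional ``poor_signal`` column;
* EDF (European Data Format), 16-bit quantized, for interoperability with
  standard EEG software.  The quality-flag series is not preserved in EDF.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecording",
    "FormatError",
    "read_recording",
    "write_recording",
    "stabilization_index",
    "PHASES",
]

PHASES = ("before", "during", "after")

#: poor-signal value at or below which the sensor is considered stabilized
STABLE_POOR_SIGNAL = 51


class FormatError(ValueError):
    """Raised when a file does not conform to the expected dialect."""


@dataclass
class EEGRecording:
    """A single-channel EEG voltage series with acquisition metadata.

    Parameters
    ----------
    samples : ndarray
        Voltage in microvolts, one value per sample.
    fs : float
        Sampling rate in Hz (default 512, the TGAM1 rate).
    channel : str
        Electrode label in 10-20 nomenclature (default ``"fp1"``).
    phase : str
        Therapy phase, one of ``before``/``during``/``after``.
    subject_id : str
        Identifier of the recorded subject.
    poor_signal : ndarray or None
        Optional per-sample quality flag, integers in [0, 255];
        lower is better.
    """

    samples: np.ndarray
    fs: float = 512.0
    channel: str = "fp1"
    phase: str = "before"
    subject_id: str = "S01"
    poor_signal: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.poor_signal is not None:
            ps = np.asarray(self.poor_signal)
            if ps.shape != self.samples.shape:
                raise ValueError("poor_signal must align with samples")
            if ps.size and (ps.min() < 0 or ps.max() > 255):
                raise ValueError("poor_signal values must lie in [0, 255]")
            self.poor_signal = ps.astype(int)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "EEGRecording":
        return replace(self, **changes)

    def stabilized(self, threshold: int = STABLE_POOR_SIGNAL) -> "EEGRecording":
        """Return the recording with pre-stabilization samples dropped.

        If no quality-flag series is present the recording is returned
        unchanged.  Raises ``ValueError`` if the flag never reaches the
        threshold (the whole recording would be discarded).
        """
        if self.poor_signal is None:
            return self
        idx = stabilization_index(self.poor_signal, threshold)
        if idx is None:
            raise ValueError("signal never stabilized; no usable samples")
        return self.copy_with(
            samples=self.samples[idx:], poor_signal=self.poor_signal[idx:]
        )


def stabilization_index(poor_signal, threshold: int = STABLE_POOR_SIGNAL):
    """First sample index at which the poor-signal flag is acceptable.

    The sensor stabilizes once the flag first registers a value less than
    or equal to *threshold* (default 51).  Returns ``None`` if the flag
    never reaches the threshold.
    """
    ps = np.asarray(poor_signal)
    if ps.size == 0:
        raise ValueError("poor_signal series is empty")
    if ps.min() < 0 or ps.max() > 255:
        raise ValueError("poor_signal values must lie in [0, 255]")
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    hits = np.nonzero(ps <= threshold)[0]
    return int(hits[0]) if hits.size else None


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^#\s*(\w+)\s*=\s*(.+?)\s*$")


def _write_csv(rec: EEGRecording, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write(f"# channel={rec.channel}\n")
        fh.write(f"# phase={rec.phase}\n")
        fh.write(f"# subject={rec.subject_id}\n")
        if rec.poor_signal is None:
            fh.write("uV\n")
            for v in rec.samples:
                fh.write(f"{float(v)!r}\n")
        else:
            fh.write("uV,poor_signal\n")
            for v, q in zip(rec.samples, rec.poor_signal):
                fh.write(f"{float(v)!r},{int(q)}\n")


def _read_csv(path: Path) -> EEGRecording:
    meta: dict[str, str] = {}
    samples: list[float] = []
    quality: list[int] = []
    has_quality = False
    with open(path) as fh:
        lineno = 0
        header_seen = False
        for raw in fh:
            lineno += 1
            line = raw.strip()
            if not line:
                continue
            m = _HEADER_RE.match(line)
            if m:
                meta[m.group(1)] = m.group(2)
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols[0] != "uV":
                    raise FormatError(
                        f"{path}:{lineno}: expected column header 'uV', got {line!r}"
                    )
                has_quality = len(cols) > 1 and cols[1] == "poor_signal"
                header_seen = True
                continue
            parts = line.split(",")
            try:
                value = float(parts[0])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric sample {parts[0]!r}"
                ) from exc
            if not np.isfinite(value):
                raise FormatError(f"{path}:{lineno}: non-finite sample {parts[0]!r}")
            samples.append(value)
            if has_quality:
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: missing poor_signal value")
                quality.append(int(parts[1]))
    if "fs" not in meta:
        raise FormatError(f"{path}: missing required header '# fs=...'")
    return EEGRecording(
        samples=np.array(samples, dtype=float),
        fs=float(meta["fs"]),
        channel=meta.get("channel", "fp1"),
        phase=meta.get("phase", "before"),
        subject_id=meta.get("subject", "S01"),
        poor_signal=np.array(quality, dtype=int) if has_quality else None,
    )


# ---------------------------------------------------------------------------
# EDF (16-bit, single channel)
# ---------------------------------------------------------------------------
# Minimal EDF codec: fixed 256-byte main header, one 256-byte signal header,
# 1-second data records of little-endian int16.  Writing requires a
# whole-second recording at an integer sampling rate; phase and subject are
# carried in the recording-identification field.

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def edf_quantization_step(phys_min: float, phys_max: float) -> float:
    """Physical value of one digital step for the given physical range."""
    return (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _write_edf(rec: EEGRecording, path: Path) -> None:
    fs = rec.fs
    if fs != int(fs):
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(fs)
    if rec.n_samples % fs != 0:
        raise ValueError("EDF export requires a whole number of seconds")
    n_records = rec.n_samples // fs

    amp = float(np.max(np.abs(rec.samples)))
    phys_max = max(amp, 1.0) * 1.0001  # avoid clipping the extreme sample
    phys_min = -phys_max
    step = edf_quantization_step(phys_min, phys_max)
    digital = np.clip(
        np.round((rec.samples - phys_min) / step) + _EDF_DIG_MIN,
        _EDF_DIG_MIN,
        _EDF_DIG_MAX,
    ).astype("<i2")

    rec_id = f"subject={rec.subject_id} phase={rec.phase}"
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad(rec_id, 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * 2), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))  # record duration, seconds
        fh.write(_pad("1", 4))
        # signal header
        fh.write(_pad(f"EEG {rec.channel}", 16))
        fh.write(_pad("", 80))
        fh.write(_pad("uV", 8))
        fh.write(_pad(f"{phys_min:.3f}"[:8], 8))
        fh.write(_pad(f"{phys_max:.3f}"[:8], 8))
        fh.write(_pad(str(_EDF_DIG_MIN), 8))
        fh.write(_pad(str(_EDF_DIG_MAX), 8))
        fh.write(_pad("", 80))
        fh.write(_pad(str(fs), 8))
        fh.write(_pad("", 32))
        fh.write(digital.tobytes())


def _read_edf(path: Path) -> EEGRecording:
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        rec_id = header[88:168].decode("ascii").strip()
        n_records = int(header[236:244])
        record_dur = float(header[244:252])
        n_signals = int(header[252:256])
        if n_signals != 1:
            raise FormatError(f"{path}: expected 1 EDF signal, found {n_signals}")
        sig = fh.read(256)
        label = sig[0:16].decode("ascii").strip()
        phys_min = float(sig[104:112])
        phys_max = float(sig[112:120])
        dig_min = int(sig[120:128])
        dig_max = int(sig[128:136])
        n_per_record = int(sig[216:224])
        payload = fh.read(2 * n_per_record * n_records)
    digital = np.frombuffer(payload, dtype="<i2").astype(float)
    step = (phys_max - phys_min) / (dig_max - dig_min)
    samples = phys_min + (digital - dig_min) * step
    meta = dict(
        m.split("=", 1) for m in rec_id.split() if "=" in m
    )
    channel = label.removeprefix("EEG").strip() or "fp1"
    return EEGRecording(
        samples=samples,
        fs=n_per_record / record_dur,
        channel=channel,
        phase=meta.get("phase", "before"),
        subject_id=meta.get("subject", "S01"),
    )


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "edf" if path.suffix.lower() == ".edf" else "csv"


def read_recording(path, format: str | None = None) -> EEGRecording:
    """Read an :class:`EEGRecording` from *path* (CSV dialect or EDF).

    The format is inferred from the file extension unless given explicitly.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_recording(rec: EEGRecording, path, format: str | None = None) -> None:
    """Write *rec* to *path*.

    CSV is lossless (full float precision, ``repr`` round-trip); EDF is
    quantized to the 16-bit grid of the format, with the physical range
    chosen to cover the recording's amplitude.
    """
    if rec.n_samples == 0:
        raise ValueError("refusing to write an empty recording")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
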