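"""Shared containers, spectral band definitions and error types.

Two channels are handled throughout the package: single-lead ECG (mV) and
skin conductance / electrodermal activity (µS). Both are represented as
uniformly sampled :class:`RawSignal` objects. Beat-to-beat cardiac data are
carried as a :class:`RRSeries` (beat times plus inter-beat intervals, with an
optional evenly resampled series for spectral analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

CONDITIONS: Tuple[str, ...] = ("BL", "PVT", "NBACK", "SS")
"""Canonical condition order: baseline, psychomotor vigilance task,
auditory n-back working memory, ship-search visual search."""


class TaskPhysioError(Exception):
    """Base class for package errors."""


class SignalQualityError(TaskPhysioError):
    """Raised when a physiological segment cannot support index extraction
    (too short, too few beats, no valid intervals...)."""


class DecompositionError(TaskPhysioError):
    """Raised when the tonic/phasic EDA decomposition fails to converge or a
    spectral normalization is undefined."""


class ConfigError(TaskPhysioError):
    """Raised for invalid configuration values (bands, rates, profiles)."""


@dataclass(frozen=True)
class RawSignal:
    """A uniformly sampled physiological channel.

    Parameters
    ----------
    samples:
        Signal values; mV for ECG, µS for EDA.
    fs:
        Sampling rate in Hz.
    channel:
        Either ``"ECG"`` or ``"EDA"``.
    """

    samples: np.ndarray
    fs: float
    channel: str = "ECG"

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if self.channel not in ("ECG", "EDA"):
            raise ConfigError(f"unknown channel {self.channel!r}")
        if self.samples.ndim != 1:
            raise ConfigError("RawSignal expects a 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise SignalQualityError("RawSignal contains non-finite samples")

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs


@dataclass
class RRSeries:
    """Beat times with inter-beat (R-R) intervals.

    ``beat_times`` are strictly increasing times in seconds; ``rr_ms`` holds
    the ``len(beat_times) - 1`` successive intervals in milliseconds. After
    :func:`taskphysio.hrv.uniform_rr`, ``uniform_times``/``uniform_rr`` carry
    the cubic-spline resampled series (at ``uniform_fs`` Hz) used for the
    averaged spectrum.
    """

    beat_times: np.ndarray
    rr_ms: np.ndarray
    uniform_fs: Optional[float] = None
    uniform_times: Optional[np.ndarray] = None
    uniform_rr: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.beat_times.size >= 2 and np.any(np.diff(self.beat_times) <= 0):
            raise SignalQualityError("beat times must be strictly increasing")
        if self.rr_ms.size != max(self.beat_times.size - 1, 0):
            raise ConfigError("rr_ms must have one fewer entry than beat_times")


def _check_band(name: str, band: Tuple[float, float]) -> None:
    lo, hi = band
    if not (0 <= lo < hi):
        raise ConfigError(f"band {name} must satisfy 0 <= low < high, got {band}")


@dataclass(frozen=True)
class SpectralBands:
    """Frequency bands (Hz) used by the spectral indices.

    lf/hf are the standard HRV low/high frequency bands; tp is the total-power
    band used to normalize HRVLFn/HRVHFn; edasymp and tvsymp are the EDA
    sympathetic-tone bands.
    """

    lf: Tuple[float, float] = (0.045, 0.15)
    hf: Tuple[float, float] = (0.15, 0.4)
    tp: Tuple[float, float] = (0.003, 0.4)
    edasymp: Tuple[float, float] = (0.045, 0.25)
    tvsymp: Tuple[float, float] = (0.08, 0.24)

    def __post_init__(self) -> None:
        for name in ("lf", "hf", "tp", "edasymp", "tvsymp"):
            _check_band(name, getattr(self, name))


def band_mask(freqs: np.ndarray, band: Tuple[float, float]) -> np.ndarray:
    """Boolean mask of frequency-grid points inside [low, high]."""
    lo, hi = band
    return (freqs >= lo) & (freqs <= hi)


def band_power(freqs: np.ndarray, psd: np.ndarray, band: Tuple[float, float]) -> float:
    """Trapezoidal integral of a one-sided PSD over a band."""
    m = band_mask(freqs, band)
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[m], freqs[m]))
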