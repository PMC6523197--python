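"""Heart rate variability indices from a 4-minute ECG segment.

Processing chain: 0.05-40 Hz band-pass filtering, R-peak detection
(derivative - squaring - moving-window integration with an adaptive
threshold, peaks refined to local maxima of the filtered signal), automatic
interval-range cleaning (250-3000 ms), cubic-spline resampling of the R-R
series to an even 4 Hz grid, Blackman-windowed averaged periodogram
(256-point segments, 50% overlap), and trapezoidal band powers:

* HRVLF (ms²): 0.045-0.15 Hz, a mixed sympathetic index;
* HRVHF (ms²): 0.15-0.4 Hz, a parasympathetic (vagal) index;
* HRVLFn / HRVHFn: the same powers normalized by total power (0.003-0.4 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from .core import (RawSignal, RRSeries, SignalQualityError, SpectralBands,
                   band_power, DecompositionError)

#: physiologically plausible inter-beat interval range (ms) used for cleaning
RR_VALID_MS = (250.0, 3000.0)

MIN_ECG_DURATION_S = 240.0
MIN_BEATS = 60


def bandpass_ecg(ecg: RawSignal, low: float = 0.05, high: float = 40.0) -> np.ndarray:
    """Zero-phase Butterworth band-pass used ahead of R-peak detection."""
    high = min(high, 0.45 * ecg.fs)
    sos = sps.butter(2, [low, high], btype="bandpass", fs=ecg.fs, output="sos")
    return sps.sosfiltfilt(sos, ecg.samples)


def detect_r_peaks(ecg: RawSignal) -> np.ndarray:
    """Detect R-peak times (s) in a single-lead ECG.

    Raises :class:`SignalQualityError` when fewer than 60 beats are found
    (a 4-minute segment at any plausible heart rate has far more).
    """
    if ecg.duration < MIN_ECG_DURATION_S:
        raise SignalQualityError(
            f"need >= {MIN_ECG_DURATION_S:.0f} s of ECG, got {ecg.duration:.1f} s")
    fs = ecg.fs
    filt = bandpass_ecg(ecg)

    # derivative -> squaring -> moving-window integration
    deriv = np.gradient(filt) * fs
    mwi = uniform_filter1d(deriv ** 2, size=max(int(0.15 * fs), 1))

    min_dist = max(int(0.25 * fs), 1)
    cand, _ = sps.find_peaks(mwi, distance=min_dist)
    if cand.size == 0:
        raise SignalQualityError("no QRS-like energy found")
    heights = mwi[cand]
    thr = 0.25 * np.percentile(heights, 90)
    cand = cand[heights > thr]

    # refine each detection to the local maximum of the filtered ECG (±100 ms)
    half = int(round(0.1 * fs))
    peaks = []
    for idx in cand:
        lo, hi = max(idx - half, 0), min(idx + half + 1, filt.size)
        peaks.append(lo + int(np.argmax(filt[lo:hi])))
    peaks = np.unique(peaks)
    # enforce refractoriness: drop the smaller of any pair closer than 200 ms
    keep = []
    for p in peaks:
        if keep and (p - keep[-1]) < 0.2 * fs:
            if filt[p] > filt[keep[-1]]:
                keep[-1] = p
        else:
            keep.append(p)
    beat_times = np.asarray(keep, dtype=float) / fs
    if beat_times.size < MIN_BEATS:
        raise SignalQualityError(
            f"only {beat_times.size} beats detected (< {MIN_BEATS}); "
            "segment failed quality screening")
    return beat_times


def uniform_rr(beat_times: np.ndarray, resample_fs: float = 4.0) -> RRSeries:
    """Clean the R-R series and resample it to an even grid by cubic spline.

    Intervals outside 250-3000 ms (ectopic or missed beats) are dropped
    before splining. The uniform grid spans [first, last] beat time at
    ``resample_fs`` Hz.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 4:
        raise SignalQualityError("need at least 4 beats to build an RR series")
    rr = np.diff(beat_times) * 1000.0
    valid = (rr > RR_VALID_MS[0]) & (rr < RR_VALID_MS[1])
    if valid.sum() < 4:
        raise SignalQualityError("fewer than 4 valid RR intervals after cleaning")
    t_rr = beat_times[1:][valid]
    rr_clean = rr[valid]
    spline = CubicSpline(t_rr, rr_clean, extrapolate=True)
    grid = np.arange(beat_times[0], beat_times[-1], 1.0 / resample_fs)
    series = spline(grid)
    return RRSeries(beat_times=beat_times, rr_ms=rr,
                    uniform_fs=resample_fs, uniform_times=grid,
                    uniform_rr=series)


@dataclass(frozen=True)
class HRVSpectrum:
    """Averaged one-sided PSD of the uniform RR series (ms²/Hz)."""

    freqs: np.ndarray
    psd: np.ndarray
    window_len: int
    n_segments: int


@dataclass(frozen=True)
class HRVIndices:
    """Band powers of the RR spectrum (ms² and normalized units)."""

    HRVLF: float
    HRVHF: float
    HRVLFn: float
    HRVHFn: float
    total_power: float


def averaged_spectrum(rr: RRSeries, window_len: int = 256,
                      overlap_frac: float = 0.5) -> HRVSpectrum:
    """Blackman-windowed averaged periodogram of the uniform RR series.

    Segments are mean-removed before windowing; the window-power
    normalization makes the integrated PSD approximate the series variance.
    """
    if rr.uniform_rr is None:
        raise SignalQualityError("call uniform_rr() before averaged_spectrum()")
    x = np.asarray(rr.uniform_rr, dtype=float)
    if x.size < window_len:
        raise SignalQualityError(
            f"series of {x.size} samples is shorter than one "
            f"{window_len}-point window")
    noverlap = int(round(window_len * overlap_frac))
    freqs, psd = sps.welch(x, fs=rr.uniform_fs, window="blackman",
                           nperseg=window_len, noverlap=noverlap,
                           detrend="constant", scaling="density")
    n_segments = 1 + (x.size - window_len) // (window_len - noverlap)
    return HRVSpectrum(freqs=freqs, psd=psd, window_len=window_len,
                       n_segments=n_segments)


def hrv_band_indices(spec: HRVSpectrum,
                     bands: SpectralBands | None = None) -> HRVIndices:
    """Integrate the averaged spectrum over the LF, HF and total-power bands."""
    bands = bands or SpectralBands()
    lf = band_power(spec.freqs, spec.psd, bands.lf)
    hf = band_power(spec.freqs, spec.psd, bands.hf)
    tp = band_power(spec.freqs, spec.psd, bands.tp)
    if tp <= 0:
        raise DecompositionError("total power is zero; normalized indices undefined")
    return HRVIndices(HRVLF=lf, HRVHF=hf, HRVLFn=lf / tp, HRVHFn=hf / tp,
                      total_power=tp)


def hrv_indices(ecg: RawSignal, bands: SpectralBands | None = None,
                resample_fs: float = 4.0) -> HRVIndices:
    """Full chain: R-peaks -> cleaned uniform RR -> averaged spectrum -> indices."""
    beats = detect_r_peaks(ecg)
    rr = uniform_rr(beats, resample_fs=resample_fs)
    spec = averaged_spectrum(rr)
    return hrv_band_indices(spec, bands)
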