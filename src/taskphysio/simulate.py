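"""Synthetic cohort generator for autonomic task-response experiments.

The study design emulated here: a cohort of subjects each performs four
conditions — seated baseline (BL), psychomotor vigilance (PVT), auditory
n-back working memory (NBACK) and a ship-search visual search (SS) — in
repeated trials across a 24-h wakefulness protocol, with single-lead ECG and
palmar skin conductance recorded per condition.

No public dataset accompanies the study, so every downstream stage is driven
by two standard minimal generative models:

* **Cardiac**: integral pulse frequency modulation (IPFM). A modulating rate
  ``m(t) = (hr/60) * (1 + a_LF sin(2π f_LF t + φ_LF) + a_HF sin(2π f_HF t + φ_HF))``
  is integrated; a beat is emitted each time the integral crosses an integer.
  This places controllable spectral power at the LF and HF bands of the
  resulting R-R series. A stereotyped biphasic QRS-like pulse train plus
  baseline wander and white noise turns beat times into an ECG waveform.
* **Electrodermal**: a slowly varying tonic level (constant + linear drift +
  sub-0.02 Hz sinusoid) plus a sparse phasic component — skin conductance
  responses (SCRs) as a Poisson event process with log-normal amplitudes
  convolved with a peak-normalized Bateman kernel (difference of
  exponentials, rise 0.75 s, decay 10 s) — plus white noise.

Condition profiles default to the published group means (tonic level,
SCR rate, modulation depths patterned on the study's summary table) so the
synthetic classification problem has comparable structure; per-subject
additive offsets provide the between-subject variance that leave-one-subject-
out cross-validation exercises.

Every generator is bit-for-bit reproducible under a fixed seed.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .core import CONDITIONS, ConfigError, RawSignal, RRSeries

logger = logging.getLogger(__name__)

#: Bateman kernel time constants (s): SCR rise and recovery.
BATEMAN_RISE_S = 0.75
BATEMAN_DECAY_S = 10.0


@dataclass(frozen=True)
class ConditionProfile:
    """Generative parameters for one experimental condition.

    Units: ``mean_hr`` beats/min; modulation depths dimensionless;
    ``f_LF``/``f_HF`` Hz; ``tonic_level`` µS; ``tonic_drift_slope`` µS/min;
    ``scr_rate`` events/min; SCR amplitudes log-normal in log-µS;
    noise SDs in mV (ECG) and µS (EDA).
    """

    condition_label: str
    mean_hr: float = 65.0
    lf_mod_amp: float = 0.07
    hf_mod_amp: float = 0.05
    f_LF: float = 0.1
    f_HF: float = 0.3
    tonic_level: float = 2.0
    tonic_drift_slope: float = 0.0
    scr_rate: float = 2.0
    scr_amp_log_mean: float = math.log(0.3)
    scr_amp_log_sd: float = 0.4
    noise_sd_ecg: float = 0.02
    noise_sd_eda: float = 0.01

    def __post_init__(self) -> None:
        if self.condition_label not in CONDITIONS:
            raise ConfigError(f"condition must be one of {CONDITIONS}")
        if not (30 < self.mean_hr < 200):
            raise ConfigError(f"mean_hr must lie in (30, 200), got {self.mean_hr}")
        if self.lf_mod_amp < 0 or self.hf_mod_amp < 0:
            raise ConfigError("modulation depths must be non-negative")
        if self.lf_mod_amp + self.hf_mod_amp >= 1:
            raise ConfigError("lf_mod_amp + hf_mod_amp must stay below 1 "
                              "(the modulated rate would touch zero)")
        if not (0.045 <= self.f_LF <= 0.15):
            raise ConfigError("f_LF must lie in the LF band 0.045-0.15 Hz")
        if not (0.15 <= self.f_HF <= 0.4):
            raise ConfigError("f_HF must lie in the HF band 0.15-0.4 Hz")
        if self.scr_rate < 0:
            raise ConfigError("scr_rate must be non-negative")


@dataclass(frozen=True)
class SubjectEffect:
    """Per-subject additive offsets, drawn once per subject.

    Offsets are applied to the numeric profile fields named in
    ``OFFSET_FIELDS`` and then clipped back into the profile's validity
    ranges, so a cohort is a set of subject-shifted condition profiles.
    """

    subject_id: str
    offsets: Dict[str, float]
    rng_seed: int


#: profile fields that receive subject offsets, with their between-subject SD
DEFAULT_OFFSET_SDS: Dict[str, float] = {
    "mean_hr": 6.0,
    "lf_mod_amp": 0.02,
    "hf_mod_amp": 0.015,
    "tonic_level": 2.4,
    "scr_rate": 0.9,
    "scr_amp_log_mean": 0.25,
}


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside each synthetic recording."""

    beat_times: Optional[np.ndarray] = None
    scr_event_times: Optional[np.ndarray] = None
    scr_event_amps: Optional[np.ndarray] = None
    tonic_curve: Optional[np.ndarray] = None
    lf_mod_amp: Optional[float] = None
    hf_mod_amp: Optional[float] = None


@dataclass
class Recording:
    """One labelled subject x trial x condition recording pair."""

    subject_id: str
    trial: int
    condition: str
    ecg: RawSignal
    eda: RawSignal
    truth_ecg: SyntheticTruth
    truth_eda: SyntheticTruth
    seed: int


# ---------------------------------------------------------------------------
# cardiac model
# ---------------------------------------------------------------------------

def generate_rr(profile: ConditionProfile, duration: float, seed: int
                ) -> Tuple[RRSeries, SyntheticTruth]:
    """Simulate an R-R interval series by integral pulse frequency modulation.

    The closed-form integral of the modulated rate is solved for successive
    integer crossings (one beat per crossing). Modulator phases are drawn
    from ``seed`` so distinct seeds give distinct beat times while leaving
    band powers — which depend on the depths only — unchanged.

    Returns the series (intervals in ms) and the ground-truth record.
    """
    if duration < 240:
        raise ConfigError("generate_rr requires at least a 240 s segment")
    r0 = profile.mean_hr / 60.0
    a_lf, a_hf = profile.lf_mod_amp, profile.hf_mod_amp
    if a_lf + a_hf >= 1:
        raise ConfigError("modulation would drive the beat rate to zero")
    w_lf = 2 * math.pi * profile.f_LF
    w_hf = 2 * math.pi * profile.f_HF
    rng = np.random.default_rng(seed)
    ph_lf, ph_hf = rng.uniform(0, 2 * math.pi, size=2)

    def integral(t: float) -> float:
        # ∫0^t m(τ) dτ with m(t) = r0 (1 + a_lf sin(w_lf t + φ) + a_hf sin(w_hf t + ψ))
        return r0 * (
            t
            + a_lf / w_lf * (math.cos(ph_lf) - math.cos(w_lf * t + ph_lf))
            + a_hf / w_hf * (math.cos(ph_hf) - math.cos(w_hf * t + ph_hf))
        )

    n_beats = int(math.floor(integral(duration)))
    beat_times = np.empty(n_beats)
    t_prev = 0.0
    max_step = 2.5 / (r0 * (1 - a_lf - a_hf))
    for k in range(1, n_beats + 1):
        hi = min(duration, t_prev + max_step)
        while integral(hi) < k and hi < duration:
            hi = min(duration, hi + max_step)
        beat_times[k - 1] = brentq(lambda t: integral(t) - k, t_prev, hi,
                                   xtol=1e-9)
        t_prev = beat_times[k - 1]

    rr_ms = np.diff(beat_times) * 1000.0
    truth = SyntheticTruth(beat_times=beat_times, lf_mod_amp=a_lf, hf_mod_amp=a_hf)
    return RRSeries(beat_times=beat_times, rr_ms=rr_ms), truth


def qrs_template(fs: float, width: float = 0.08, amplitude: float = 1.0) -> np.ndarray:
    """Biphasic QRS-like pulse: a Ricker (Mexican-hat) wavelet, peak at centre."""
    a = width / 5.0  # characteristic scale; support ~ ±width/2
    half = int(round(0.06 * fs))
    t = np.arange(-half, half + 1) / fs
    w = (1 - (t / a) ** 2) * np.exp(-(t ** 2) / (2 * a ** 2))
    return amplitude * w


def synthesize_ecg(rr: RRSeries, fs: float = 256.0, seed: int = 0, *,
                   noise_sd: float = 0.02, wander_amp: float = 0.1,
                   wander_freq: float = 0.25, qrs_amp: float = 1.0,
                   duration: Optional[float] = None) -> RawSignal:
    """Render beat times as an ECG-like waveform.

    A stereotyped ~80 ms biphasic pulse (1 mV peak by default) is placed at
    each beat time, on top of a slow baseline-wander sinusoid (< 0.3 Hz) and
    white noise. Not a morphological ECG model — just enough structure for an
    R-peak detector to have honest work to do.
    """
    if fs < 128:
        raise ConfigError("ECG synthesis requires fs >= 128 Hz")
    if wander_freq > 0.3:
        raise ConfigError("baseline wander must stay below 0.3 Hz")
    if duration is None:
        duration = float(rr.beat_times[-1]) + 1.0
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    sig = np.zeros(n)
    tmpl = qrs_template(fs, amplitude=qrs_amp)
    half = (tmpl.size - 1) // 2
    for bt in rr.beat_times:
        idx = int(round(bt * fs))
        lo, hi = idx - half, idx + half + 1
        s_lo, s_hi = max(lo, 0), min(hi, n)
        if s_lo >= s_hi:
            continue
        sig[s_lo:s_hi] += tmpl[s_lo - lo: tmpl.size - (hi - s_hi)]
    t = np.arange(n) / fs
    if wander_amp > 0:
        sig += wander_amp * np.sin(2 * math.pi * wander_freq * t
                                   + rng.uniform(0, 2 * math.pi))
    if noise_sd > 0:
        sig += rng.normal(0.0, noise_sd, size=n)
    return RawSignal(samples=sig, fs=fs, channel="ECG")


# ---------------------------------------------------------------------------
# electrodermal model
# ---------------------------------------------------------------------------

def bateman_kernel(t: np.ndarray, rise: float = BATEMAN_RISE_S,
                   decay: float = BATEMAN_DECAY_S) -> np.ndarray:
    """Peak-normalized Bateman impulse response, zero for t < 0."""
    t = np.asarray(t, dtype=float)
    h = np.where(t >= 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * math.log(decay / rise)
    peak = math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
    return h / peak


def synthesize_eda(profile: ConditionProfile, duration: float, fs: float = 8.0,
                   seed: int = 0, *, slow_amp: float = 0.1,
                   slow_freq: float = 0.015,
                   events: Optional[Tuple[Sequence[float], Sequence[float]]] = None
                   ) -> Tuple[RawSignal, SyntheticTruth]:
    """Simulate a skin-conductance recording.

    tonic (level + drift + slow sinusoid) + Σ aᵢ·h(t−tᵢ) + white noise, with
    SCR onsets tᵢ from a Poisson process of ``profile.scr_rate`` events/min
    and log-normal amplitudes aᵢ. Pass ``events=(times, amps)`` to pin the
    phasic events instead of drawing them (used by recovery tests).
    """
    if duration < 120:
        raise ConfigError("synthesize_eda requires at least a 120 s segment")
    if slow_freq >= 0.02:
        raise ConfigError("tonic sinusoid must stay below 0.02 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    tonic = (profile.tonic_level
             + profile.tonic_drift_slope * t / 60.0)
    if slow_amp > 0:
        tonic = tonic + slow_amp * np.sin(2 * math.pi * slow_freq * t
                                          + rng.uniform(0, 2 * math.pi))

    if events is not None:
        ev_times = np.asarray(events[0], dtype=float)
        ev_amps = np.asarray(events[1], dtype=float)
    else:
        n_ev = rng.poisson(profile.scr_rate * duration / 60.0)
        ev_times = np.sort(rng.uniform(0.0, duration, size=n_ev))
        ev_amps = rng.lognormal(profile.scr_amp_log_mean,
                                profile.scr_amp_log_sd, size=n_ev)
    if np.any(ev_amps <= 0):
        raise ConfigError("SCR amplitudes must be positive")

    phasic = np.zeros(n)
    for ti, ai in zip(ev_times, ev_amps):
        phasic += ai * bateman_kernel(t - ti)

    sig = tonic + phasic
    if profile.noise_sd_eda > 0:
        sig = sig + rng.normal(0.0, profile.noise_sd_eda, size=n)
    truth = SyntheticTruth(scr_event_times=ev_times, scr_event_amps=ev_amps,
                           tonic_curve=tonic)
    return RawSignal(samples=sig, fs=fs, channel="EDA"), truth


# ---------------------------------------------------------------------------
# condition profiles and cohorts
# ---------------------------------------------------------------------------

def default_profiles() -> Dict[str, ConditionProfile]:
    """Condition profiles patterned on the study's group summary table.

    Tonic levels and SCR rates take the published condition means directly
    (SCL 0.19/3.5/4.6/5.6 µS; NS.SCRs 2.1/3.1/2.1/2.5 per min); modulation
    depths are chosen so the normalized LF index is lowest under n-back and
    comparable across BL/PVT/SS, mirroring the published ordering.
    """
    return {
        "BL": ConditionProfile("BL", mean_hr=62, lf_mod_amp=0.060,
                               hf_mod_amp=0.048, tonic_level=0.19,
                               scr_rate=2.1, scr_amp_log_mean=math.log(0.25)),
        "PVT": ConditionProfile("PVT", mean_hr=68, lf_mod_amp=0.075,
                                hf_mod_amp=0.058, tonic_level=3.5,
                                scr_rate=3.1, scr_amp_log_mean=math.log(0.35)),
        "NBACK": ConditionProfile("NBACK", mean_hr=66, lf_mod_amp=0.042,
                                  hf_mod_amp=0.038, tonic_level=4.6,
                                  scr_rate=2.1, scr_amp_log_mean=math.log(0.22)),
        "SS": ConditionProfile("SS", mean_hr=65, lf_mod_amp=0.070,
                               hf_mod_amp=0.045, tonic_level=5.6,
                               scr_rate=2.5, scr_amp_log_mean=math.log(0.45)),
    }


def well_separated_profiles() -> Dict[str, ConditionProfile]:
    """Condition profiles with between-condition gaps far exceeding the
    extraction noise, for separability controls (expected near-perfect LOSO
    accuracy when combined with small subject offsets)."""
    return {
        "BL": ConditionProfile("BL", mean_hr=55, lf_mod_amp=0.03,
                               hf_mod_amp=0.10, tonic_level=0.5,
                               scr_rate=0.5, scr_amp_log_mean=math.log(0.2)),
        "PVT": ConditionProfile("PVT", mean_hr=70, lf_mod_amp=0.14,
                                hf_mod_amp=0.03, tonic_level=4.0,
                                scr_rate=3.0, scr_amp_log_mean=math.log(0.4)),
        "NBACK": ConditionProfile("NBACK", mean_hr=85, lf_mod_amp=0.05,
                                  hf_mod_amp=0.16, tonic_level=8.0,
                                  scr_rate=6.0, scr_amp_log_mean=math.log(0.7)),
        "SS": ConditionProfile("SS", mean_hr=100, lf_mod_amp=0.17,
                               hf_mod_amp=0.08, tonic_level=12.0,
                               scr_rate=9.0, scr_amp_log_mean=math.log(1.1)),
    }


def _clip_updates(updates: Dict[str, float]) -> Dict[str, float]:
    """Clip shifted profile fields back into their validity ranges before a
    profile is constructed (construction itself validates invariants)."""
    out = dict(updates)
    if "mean_hr" in out:
        out["mean_hr"] = min(max(out["mean_hr"], 35.0), 190.0)
    lf = min(max(out.get("lf_mod_amp", 0.0), 0.005), 0.6)
    hf = min(max(out.get("hf_mod_amp", 0.0), 0.005), 0.6)
    if lf + hf >= 0.9:
        scale = 0.9 / (lf + hf)
        lf, hf = lf * scale, hf * scale
    if "lf_mod_amp" in out:
        out["lf_mod_amp"] = lf
    if "hf_mod_amp" in out:
        out["hf_mod_amp"] = hf
    if "tonic_level" in out:
        out["tonic_level"] = max(out["tonic_level"], 0.05)
    if "scr_rate" in out:
        out["scr_rate"] = max(out["scr_rate"], 0.1)
    return out


def draw_subject_effects(n_subjects: int, seed: int,
                         offset_sds: Optional[Dict[str, float]] = None
                         ) -> List[SubjectEffect]:
    """Draw one additive offset vector per subject (seeded, reproducible)."""
    sds = DEFAULT_OFFSET_SDS if offset_sds is None else offset_sds
    effects = []
    for i in range(n_subjects):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(100, i))
        rng = np.random.default_rng(ss)
        offsets = {k: float(rng.normal(0.0, sd)) for k, sd in sds.items()}
        effects.append(SubjectEffect(subject_id=f"S{i + 1:02d}", offsets=offsets,
                                     rng_seed=int(ss.generate_state(1)[0] % 2**31)))
    return effects


def apply_subject_effect(profile: ConditionProfile, effect: SubjectEffect
                         ) -> ConditionProfile:
    """Shift a condition profile by one subject's offsets (clipped back
    into the profile's validity ranges)."""
    updates = {k: getattr(profile, k) + v for k, v in effect.offsets.items()}
    if "lf_mod_amp" not in updates:
        updates["lf_mod_amp"] = profile.lf_mod_amp
    if "hf_mod_amp" not in updates:
        updates["hf_mod_amp"] = profile.hf_mod_amp
    return replace(profile, **_clip_updates(updates))


def attenuate_separation(profiles: Dict[str, ConditionProfile], factor: float
                         ) -> Dict[str, ConditionProfile]:
    """Shrink between-condition differences toward the grand mean.

    ``factor`` = 1 leaves the profiles untouched; 0 collapses all conditions
    onto their across-condition mean. Models the attenuated autonomic
    task response seen late in a sustained-wakefulness protocol.
    """
    if not (0 <= factor <= 1):
        raise ConfigError("attenuation factor must lie in [0, 1]")
    if factor == 1.0:
        return dict(profiles)
    fields = ["mean_hr", "lf_mod_amp", "hf_mod_amp", "tonic_level",
              "scr_rate", "scr_amp_log_mean"]
    means = {f: float(np.mean([getattr(p, f) for p in profiles.values()]))
             for f in fields}
    out = {}
    for cond, p in profiles.items():
        updates = {f: means[f] + factor * (getattr(p, f) - means[f])
                   for f in fields}
        out[cond] = replace(p, **_clip_updates(updates))
    return out


def iter_cohort(n_subjects: int, n_trials: int,
                profiles: Dict[str, ConditionProfile], seed: int, *,
                offset_sds: Optional[Dict[str, float]] = None,
                fatigue_trial: Optional[int] = None,
                fatigue_factor: float = 1.0,
                duration_ecg: float = 240.0, duration_eda: float = 120.0,
                fs_ecg: float = 256.0, fs_eda: float = 8.0
                ) -> Iterator[Recording]:
    """Yield labelled recordings for subject x trial x condition, streaming.

    Trials at or beyond ``fatigue_trial`` use condition profiles shrunk
    toward their grand mean by ``fatigue_factor`` (see
    :func:`attenuate_separation`); by default no attenuation is applied.
    """
    if n_subjects < 2:
        raise ConfigError("a cohort needs at least 2 subjects")
    missing = [c for c in CONDITIONS if c not in profiles]
    if missing:
        raise ConfigError(f"profiles missing conditions: {missing}")
    effects = draw_subject_effects(n_subjects, seed, offset_sds)
    ids = [e.subject_id for e in effects]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate subject_id in cohort")

    for trial in range(1, n_trials + 1):
        trial_profiles = profiles
        if fatigue_trial is not None and trial >= fatigue_trial:
            trial_profiles = attenuate_separation(profiles, fatigue_factor)
        for si, eff in enumerate(effects):
            for ci, cond in enumerate(CONDITIONS):
                prof = apply_subject_effect(trial_profiles[cond], eff)
                ss = np.random.SeedSequence(entropy=seed,
                                            spawn_key=(si, trial, ci))
                s_rr, s_ecg, s_eda = [int(x % 2**31)
                                      for x in ss.generate_state(3)]
                rr, truth_ecg = generate_rr(prof, duration_ecg, s_rr)
                ecg = synthesize_ecg(rr, fs=fs_ecg, seed=s_ecg,
                                     noise_sd=prof.noise_sd_ecg,
                                     duration=duration_ecg)
                eda, truth_eda = synthesize_eda(prof, duration_eda, fs=fs_eda,
                                                seed=s_eda)
                yield Recording(subject_id=eff.subject_id, trial=trial,
                                condition=cond, ecg=ecg, eda=eda,
                                truth_ecg=truth_ecg, truth_eda=truth_eda,
                                seed=s_rr)


def generate_cohort(n_subjects: int, n_trials: int,
                    profiles: Dict[str, ConditionProfile], seed: int,
                    **kwargs) -> List[Recording]:
    """Materialized version of :func:`iter_cohort` (see there for options)."""
    return list(iter_cohort(n_subjects, n_trials, profiles, seed, **kwargs))


# ---------------------------------------------------------------------------
# cohort directory I/O
# ---------------------------------------------------------------------------

def write_cohort(recordings: Iterable[Recording], outdir: Path | str) -> Path:
    """Write a cohort directory: per-recording two-column CSVs (time_s,
    value), a JSON truth sidecar per recording, and a manifest CSV listing
    subject, trial, condition, channel, sampling rate, file and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        stem = f"{rec.subject_id}_t{rec.trial:02d}_{rec.condition}"
        for channel, sig in (("ECG", rec.ecg), ("EDA", rec.eda)):
            fname = f"{stem}_{channel}.csv"
            t = sig.times()
            with open(outdir / fname, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["time_s", "value"])
                for ti, vi in zip(t, sig.samples):
                    w.writerow([f"{ti:.6f}", f"{vi:.6f}"])
            rows.append({"subject_id": rec.subject_id, "trial": rec.trial,
                         "condition": rec.condition, "channel": channel,
                         "fs_hz": sig.fs, "file": fname, "seed": rec.seed})
        truth = {
            "beat_times": _tolist(rec.truth_ecg.beat_times),
            "scr_event_times": _tolist(rec.truth_eda.scr_event_times),
            "scr_event_amps": _tolist(rec.truth_eda.scr_event_amps),
            "tonic_mean": (None if rec.truth_eda.tonic_curve is None
                           else float(np.mean(rec.truth_eda.tonic_curve))),
            "lf_mod_amp": rec.truth_ecg.lf_mod_amp,
            "hf_mod_amp": rec.truth_ecg.hf_mod_amp,
        }
        with open(outdir / f"{stem}_truth.json", "w") as fh:
            json.dump(truth, fh)
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["subject_id", "trial", "condition",
                                           "channel", "fs_hz", "file", "seed"])
        w.writeheader()
        w.writerows(rows)
    logger.info("wrote cohort with %d channel files to %s", len(rows), outdir)
    return outdir


def read_cohort(indir: Path | str) -> List[Recording]:
    """Read a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    groups: Dict[Tuple[str, int, str], Dict[str, dict]] = {}
    with open(indir / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["subject_id"], int(row["trial"]), row["condition"])
            groups.setdefault(key, {})[row["channel"]] = row
    out = []
    for (sid, trial, cond), chans in sorted(groups.items()):
        sigs = {}
        for channel, row in chans.items():
            data = np.loadtxt(indir / row["file"], delimiter=",", skiprows=1)
            sigs[channel] = RawSignal(samples=data[:, 1],
                                      fs=float(row["fs_hz"]), channel=channel)
        truth_path = indir / f"{sid}_t{trial:02d}_{cond}_truth.json"
        t_ecg, t_eda = SyntheticTruth(), SyntheticTruth()
        if truth_path.exists():
            with open(truth_path) as fh:
                tr = json.load(fh)
            t_ecg = SyntheticTruth(beat_times=_toarr(tr.get("beat_times")),
                                   lf_mod_amp=tr.get("lf_mod_amp"),
                                   hf_mod_amp=tr.get("hf_mod_amp"))
            t_eda = SyntheticTruth(scr_event_times=_toarr(tr.get("scr_event_times")),
                                   scr_event_amps=_toarr(tr.get("scr_event_amps")))
        out.append(Recording(subject_id=sid, trial=trial, condition=cond,
                             ecg=sigs["ECG"], eda=sigs["EDA"],
                             truth_ecg=t_ecg, truth_eda=t_eda,
                             seed=int(chans["ECG"]["seed"])))
    return out


def _tolist(a: Optional[np.ndarray]):
    return None if a is None else np.asarray(a, dtype=float).tolist()


def _toarr(x):
    return None if x is None else np.asarray(x, dtype=float)
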