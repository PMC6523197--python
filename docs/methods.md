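# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Study design being emulated

A cohort of subjects performs four conditions per trial — baseline (BL),
psychomotor vigilance (PVT), auditory n-back, ship-search (SS) — with
single-lead ECG and palmar skin conductance recorded. Trials repeat every
two hours across a 24-h wakefulness protocol (12 trials). Per condition,
the first 4 minutes of ECG and the first 2 minutes of EDA are analyzed.
Since no such dataset is publicly deposited, all inputs are simulated; the
generator is first-class, tested code, not a fixture.

## Generative models

**Cardiac.** Beat times follow integral pulse frequency modulation: the
rate `m(t) = (hr/60)(1 + a_LF sin(2π f_LF t + φ_LF) + a_HF sin(2π f_HF t + φ_HF))`
is integrated and a beat fires at each integer crossing. `f_LF = 0.1 Hz`
and `f_HF = 0.3 Hz` sit mid-band; depths `a_LF, a_HF` control LF/HF power.
Crossings are solved by bracketed root-finding on the closed-form integral
(xtol 1e-9). Phases are drawn per seed: they leave band powers unchanged but
make beat times seed-dependent, so same-profile subjects are not clones.
The ECG waveform is a Ricker (biphasic, ~80 ms, 1 mV) pulse at each beat
plus a <0.3 Hz baseline-wander sinusoid and white noise. This is *not* a
morphological PQRST model; it exists so the R-peak detector does honest
work.

**Electrodermal.** `signal = tonic + Σ aᵢ h(t − tᵢ) + noise`, with tonic =
level + linear drift + a sub-0.02 Hz sinusoid, SCR onsets tᵢ a Poisson
process (rate in events/min), amplitudes log-normal, and `h` a
peak-normalized Bateman kernel (difference of exponentials, rise 0.75 s,
decay 10 s — typical literature values, configurable).

**Cohort structure.** Condition profiles default to the published group
means where these exist (tonic levels 0.19/3.5/4.6/5.6 µS, SCR rates
2.1/3.1/2.1/2.5 per min) with modulation depths chosen so the normalized
LF index is lowest under n-back, mirroring the published ordering.
Between-subject variance comes from per-subject additive offsets drawn once
per subject (SDs patterned on the published between-subject spreads),
clipped back into physical ranges — in particular the tonic level is floored
at 0.05 µS, since conductance cannot be negative even though the published
baseline mean ± SD (0.19 ± 3.9 µS, from a device zeroed per trial) admits
negative values. A "fatigue" knob shrinks all condition profiles toward
their grand mean by a factor (default 0.6 from trial 8 on), emulating the
attenuated autonomic task response seen late in sustained wakefulness; set
`fatigue_trial=None` for a stationary cohort.

All generators are bit-for-bit reproducible: every recording's streams are
derived from `SeedSequence(seed, spawn_key=(subject, trial, condition))`.

## Index extraction

**HRV.** 0.05–40 Hz zero-phase Butterworth band-pass; R-peaks by a
derivative–squaring–moving-window-integration detector (150 ms window,
adaptive threshold at 0.25 × the 90th percentile of candidate peak heights,
250 ms refractory), each detection refined to the local maximum of the
filtered signal within ±100 ms. Fewer than 60 beats is a quality error.
Intervals outside 250–3000 ms are removed automatically (replacing the
study's manual beat inspection); the cleaned series is cubic-spline
resampled to 4 Hz. Spectra: mean-removed 256-point Blackman segments, 50%
overlap (the overlap is unstated for HRV in the source description; 50% is
adopted to mirror the EDA setting), averaged with window-power
normalization so the integrated PSD approximates the series variance. Band
powers by trapezoid over LF 0.045–0.15, HF 0.15–0.4, total 0.003–0.4 Hz;
normalized indices divide by total power. The total-power band includes a
VLF floor because normalized indices summing to 1 would make LFn/HFn
redundant; with the narrowband IPFM generator there is little true VLF
energy, so synthetic HRVLFn runs higher (~0.4–0.8) than typical human
values. Synthetic HRVLF/HRVHF magnitudes (10²–10³ ms²) are likewise not
calibrated to the published table, whose ~10 ms² scale is not reproducible
from the text; raw ms² are reported.

**EDA decomposition.** The 8 Hz signal is fit to a dictionary of slow tonic
atoms (constant, ramp, half-range cosines and sines up to ~0.033 Hz — all
below the 0.05 Hz tonic/phasic split; the sine terms give the basis
non-zero slope at the segment edges) plus Bateman kernels shifted every 0.5
s and truncated at 40 s. Fitting alternates a non-negative L1-penalized
(coordinate-descent, α = 1e-3) fit of the kernel coefficients with a
least-squares refit of the tonic atoms, started from a rolling
10th-percentile tonic estimate; the selected support is then debiased by
non-negative least squares so event amplitudes are not shrunk. The α
default keeps the residual well under 1% of signal variance on noiseless
synthetic input. A residual above 25% of the signal's deviation norm raises
a non-convergence error. Contiguous supra-zero coefficient runs (merged
within 1 s) form one SCR event; its amplitude is the peak of its own kernel
reconstruction — measured on the reconstruction, not the raw signal, so
tonic drift does not contaminate it. SCL = mean tonic; NS.SCRs counts
events above 0.05 µS per minute.

**EDA spectra.** EDASymp: Welch on the 2 Hz-resampled signal (mean-removed
128-point Blackman segments, 50% overlap), trapezoid-integrated over
0.045–0.25 Hz. The 2 Hz working rate for the spectral indices follows the
convention of the EDA sympathetic-spectrum literature and keeps the
Blackman main lobe (±3 bins ≈ ±0.047 Hz) narrow relative to the band; at
8 Hz the same 128-point window would smear a 0.1 Hz line far outside the
band. TVSymp: the mean-removed signal is normalized to unit variance and
decomposed by a fixed-band complex demodulation bank (centres k × 0.08 Hz,
zero-phase FIR low-pass at 0.04 Hz, reflect padding; the second
frequency-refinement stage of full VFCDM is omitted because components are
selected by band, not tracked); components overlapping 0.08–0.24 Hz are
summed and TVSymp is the time-mean of the analytic-signal amplitude of
that sum. Normalizing the *input* (rather than the summed component) is
what makes the index selective: an out-of-band signal then contributes only
filter leakage, and a constant input is 0 by definition. A pure in-band
sinusoid gives √2 ≈ 1.414; realistic EDA gives ~0.3–0.5 because only part
of its unit variance lies in-band.

## Statistics

Per index across the four conditions: one-sample KS normality on
standardized values (anti-conservative in the Lilliefors sense — a warning
is logged, and the test applied as specified), classical one-way ANOVA
(reported as F = 0, p = 1 in the degenerate all-identical case), and all 6
pairwise *paired* t-tests — subjects are matched by design — significant at
α/6 (Bonferroni per index; the correction span is configurable). Markers:
`*` vs BL, `†` vs PVT, `‡` vs n-back. The paired stage is considerably more
powerful than the unpaired ANOVA when subject offsets dominate, so markers
can appear at modest ANOVA p-values.

## Classification

Canonical feature order: SCL, NS_SCRs, EDASymp, TVSymp, HRVLF, HRVLFn,
HRVHF, HRVHFn. Features are z-scored with training-fold statistics only
(γ = 2.6 for the Gaussian SVM is only meaningful on a standardized scale;
the exact scaling behind the published value is unknowable, per-fold
z-scoring is this package's choice). KNN uses Euclidean distance; SVMs use
scikit-learn's one-vs-one multiclass; the tree is CART/Gini without a depth
limit (included although absent from the published best-model table);
LDA/QDA use uniform priors; Mahalanobis-QDA assigns the class minimizing
the Mahalanobis distance under class-specific covariances, ridge-
regularized (1e-6 × mean variance) when ill-conditioned. A covariance that
is singular even after regularization raises an error naming the class —
realistically triggered by QDA when a quantized index (NS.SCRs on a 2-min
window is a multiple of 0.5/min) is constant within a class; the pipeline
logs and excludes such a family from its report rather than voiding the
run. LOSO folds are one per subject; the subset search evaluates all 255
non-empty subsets, sorts by accuracy with ties broken by fewer features
then canonical order, and re-verifies the winner with an independent run.
Temporal generalization trains one model on all trial-1 samples and scores
each later trial without retraining.

## Problem sizes and runtime

The default experiment (16 subjects × 12 trials × 4 conditions = 768
recordings; 240 s ECG at 256 Hz, 120 s EDA at 8 Hz; 7 classifiers × 255
subsets) runs in about a minute on one CPU, dominated by the per-recording
sparse deconvolution (~20 ms warm) and the 255-subset LOSO searches.
Tests and the acceptance script use these same sizes or smaller.

## What the synthetic cohort does and does not show

Passing tests establish that each stage recovers the structure its own
generative model plants — spectral ratios, event counts and amplitudes,
tonic levels, separable condition profiles, chance-level behaviour under
permutation — and that the full pipeline is deterministic and leak-free.
They do not establish human-data performance: the generator has
sinusoidal (not broadband) cardiac modulation, no respiration or movement
artifacts, stereotyped SCR shape, Gaussian subject effects, and a single
scalar fatigue mechanism. Published accuracies from real cohorts are
therefore report-format references, not targets; that the default synthetic
cohort lands in a similar accuracy range (~55–66% best-model LOSO) reflects
the choice of condition separations, not a validation against the human
data.

## Known limitations

* The R-peak detector is validated against the package's own waveform
  model only; real ECG with ectopy or electrode artifacts will need the
  interval-range cleaning to do more work.
* SparsEDA-style decomposition hyperparameters (dictionary granularity,
  sparsity weight, iteration count) are exposed but tuned on noiseless
  synthetic signals.
* VFCDM omits instantaneous-frequency refinement; components are fixed
  bands.
* The KS screen with estimated parameters is anti-conservative; a
  Lilliefors table or Shapiro–Wilk would be stricter choices.
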