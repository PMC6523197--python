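# taskphysio

Identify which cognitive task a person is performing from their autonomic
nervous system response, measured non-invasively through heart rate
variability (HRV) and electrodermal activity (EDA).

The package targets the four-condition psychophysiology design used in
sustained-wakefulness studies — seated **baseline (BL)**, **psychomotor
vigilance task (PVT)**, auditory **n-back** working memory, and a
**ship-search (SS)** continuous visual search — repeated over many trials of
a 24-h protocol. It provides, as a tested, reusable pipeline:

* a **synthetic cohort generator** (no public dataset exists for this
  design): cardiac beat times from an integral pulse frequency modulation
  (IPFM) model with controllable LF/HF spectral structure, rendered as an
  ECG-like waveform, and skin conductance as tonic drift plus a sparse
  Poisson process of Bateman-kernel skin conductance responses (SCRs);
* extraction of the **8 canonical autonomic indices** per recording:

  | index | units | meaning |
  |---|---|---|
  | SCL | µS | mean tonic skin conductance level |
  | NS.SCRs | /min | non-specific SCRs above 0.05 µS |
  | EDASymp | µS² | EDA band power, 0.045–0.25 Hz |
  | TVSymp | n.u. | mean instantaneous amplitude of 0.08–0.24 Hz VFCDM components |
  | HRVLF, HRVHF | ms² | RR spectral power, 0.045–0.15 / 0.15–0.4 Hz |
  | HRVLFn, HRVHFn | n.u. | the same, normalized by total power |

* a **repeated-measurements comparison** (KS normality screen, one-way
  ANOVA, Bonferroni-corrected paired t-tests with the `* † ‡` marker
  convention);
* **task classification** with seven classifier families — KNN (k = 1),
  linear and Gaussian SVM (C = 1, γ = 2.6), CART, LDA, QDA and
  Mahalanobis-distance QDA — under leave-one-subject-out (LOSO)
  cross-validation, with exhaustive search over all 2⁸ − 1 = 255 feature
  subsets and a temporal-generalization evaluation (train on trial 1, test
  on each later trial).

The HRV chain follows the standard recipe: 0.05–40 Hz band-pass, R-peak
detection, interval cleaning (250–3000 ms), cubic-spline resampling to 4 Hz,
and a Blackman-windowed (256-point, 50% overlap) averaged periodogram. The
EDA chain uses a non-negative sparse deconvolution onto a dictionary of slow
tonic atoms plus shifted Bateman kernels (rise 0.75 s, decay 10 s) for
SCL/NS.SCRs, Welch periodograms (128-point Blackman) for EDASymp, and
variable frequency complex demodulation (VFCDM) for TVSymp.

## Worked example

`examples/` contains one narrative script per capability. For instance
classification (`python examples/04_task_classification.py`):

```
KNN (k=1), all 8 indices: LOSO accuracy 55.0% (chance level 25%)
Confusion matrix (rows = true condition):
       BL  PVT  NBACK  SS
BL      5    2      3   0
PVT     2    5      1   2
NBACK   2    1      7   0
SS      1    4      0   5

Exhaustive search over 255 subsets; top 3:
   62.5%  SCL, EDASymp, HRVLF, HRVLFn, HRVHF, HRVHFn
   57.5%  SCL, EDASymp, TVSymp, HRVLF, HRVHF
   57.5%  SCL, EDASymp, HRVLF, HRVLFn, HRVHFn
```

Each held-out subject's four recordings are classified by a model trained
on the other nine subjects; 55% against a 25% chance level means the
autonomic indices carry substantial task information, and the subset search
shows it is maximized by combining skin-conductance and cardiac indices.

The full experiment — simulate a 16-subject × 12-trial cohort, extract all
768 × 8 indices, compare, classify and evaluate temporal generalization —
is one call (or `taskphysio run-all` from the shell):

```python
from taskphysio import RunConfig, run_experiment
result = run_experiment(RunConfig(seed=1, outdir="my_run"))
```

which writes `features.csv`, the comparison table, per-classifier best
subsets, confusion matrices, the per-trial accuracy curve, and a
`config.yaml` + run log capturing every seed and parameter.

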