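"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: the IPFM oracle
integrates the modulated rate on a dense 1 kHz grid and interpolates integer
crossings; the spectral ratio oracle uses a plain unwindowed periodogram;
the classifier oracles are brute-force distance computations and the
plug-in Gaussian discriminant in closed form.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline


def dense_ipfm_beats(mean_hr: float, a_lf: float, a_hf: float,
                     f_lf: float, f_hf: float, duration: float,
                     ph_lf: float = 0.0, ph_hf: float = 0.0,
                     grid_fs: float = 1000.0) -> np.ndarray:
    """Beat times from dense numerical integration of the IPFM equations."""
    t = np.arange(0.0, duration, 1.0 / grid_fs)
    m = (mean_hr / 60.0) * (1.0
                            + a_lf * np.sin(2 * np.pi * f_lf * t + ph_lf)
                            + a_hf * np.sin(2 * np.pi * f_hf * t + ph_hf))
    assert np.all(m > 0), "modulation drives the rate non-positive"
    M = cumulative_trapezoid(m, t, initial=0.0)
    ks = np.arange(1, int(np.floor(M[-1])) + 1)
    return np.interp(ks, M, t)


def plain_lf_hf_ratio(beat_times: np.ndarray, resample_fs: float = 4.0,
                      lf=(0.045, 0.15), hf=(0.15, 0.4)) -> float:
    """LF/HF power ratio via spline resampling + raw periodogram (no window,
    no averaging) — an estimator independent of the package's Welch path."""
    rr = np.diff(beat_times) * 1000.0
    tb = beat_times[1:]
    grid = np.arange(tb[0], beat_times[-1], 1.0 / resample_fs)
    x = CubicSpline(tb, rr)(grid)
    x = x - x.mean()
    f = np.fft.rfftfreq(x.size, 1.0 / resample_fs)
    p = np.abs(np.fft.rfft(x)) ** 2
    p_lf = p[(f >= lf[0]) & (f <= lf[1])].sum()
    p_hf = p[(f >= hf[0]) & (f <= hf[1])].sum()
    return p_lf / p_hf


def knn1_predict(train_X: np.ndarray, train_y: np.ndarray,
                 test_X: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-neighbour labels under Euclidean distance."""
    out = []
    for x in test_X:
        d = np.sqrt(((train_X - x) ** 2).sum(axis=1))
        out.append(train_y[int(np.argmin(d))])
    return np.asarray(out)


def lda_two_class_predict(train_X: np.ndarray, train_y: np.ndarray,
                          test_X: np.ndarray) -> np.ndarray:
    """Closed-form plug-in Fisher/Gaussian linear discriminant, equal priors.

    delta_k(x) = x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 with the pooled
    within-class covariance S; predictions are argmax over the two classes.
    """
    classes = np.unique(train_y)
    assert classes.size == 2
    mus, pooled = [], np.zeros((train_X.shape[1], train_X.shape[1]))
    n = 0
    for c in classes:
        Xc = train_X[train_y == c]
        mus.append(Xc.mean(axis=0))
        pooled += (Xc - Xc.mean(axis=0)).T @ (Xc - Xc.mean(axis=0))
        n += Xc.shape[0]
    S = pooled / (n - classes.size)
    Sinv = np.linalg.inv(S)
    scores = np.column_stack([
        test_X @ Sinv @ mu - 0.5 * mu @ Sinv @ mu for mu in mus])
    return classes[np.argmax(scores, axis=1)]


def oneway_anova_f(groups) -> float:
    """One-way ANOVA F from explicit sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)
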