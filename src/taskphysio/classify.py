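"""Task classification from the 8 autonomic indices.

Seven classifier families are evaluated under leave-one-subject-out (LOSO)
cross-validation on the canonical feature vector
(SCL, NS_SCRs, EDASymp, TVSymp, HRVLF, HRVLFn, HRVHF, HRVHFn):

* KNN (k = 1, Euclidean on standardized features)
* linear SVM (C = 1) and Gaussian SVM (C = 1, γ = 2.6)
* CART decision tree (Gini, no depth limit)
* LDA and QDA with uniform priors
* Mahalanobis QDA: assign the class with the smallest Mahalanobis distance
  under class-specific (ridge-regularized when ill-conditioned) covariances.

Features are z-scored with training-fold statistics only. ``subset_search``
evaluates all 255 non-empty index subsets; ``temporal_generalization``
trains on trial 1 and scores each later trial without retraining.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CONDITIONS, ConfigError

logger = logging.getLogger(__name__)

#: canonical feature order
FEATURE_NAMES: Tuple[str, ...] = ("SCL", "NS_SCRs", "EDASymp", "TVSymp",
                                  "HRVLF", "HRVLFn", "HRVHF", "HRVHFn")

CLASSIFIER_FAMILIES: Tuple[str, ...] = ("KNN", "LSVM", "GSVM", "TREE",
                                        "LDA", "QDA", "MQDA")


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its (fixed) hyperparameters."""

    family: str
    k: int = 1
    C: float = 1.0
    gamma: float = 2.6
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ConfigError(f"unknown classifier family {self.family!r}; "
                              f"choose from {CLASSIFIER_FAMILIES}")

    def metadata(self) -> Dict[str, object]:
        md: Dict[str, object] = {"family": self.family}
        if self.family == "KNN":
            md["k"] = self.k
        elif self.family == "GSVM":
            md.update(C=self.C, gamma=self.gamma)
        elif self.family == "LSVM":
            md["C"] = self.C
        return md


class MahalanobisQDA:
    """Minimum-Mahalanobis-distance classifier with class covariances.

    Unlike QDA it drops the log-determinant and prior terms: a sample is
    assigned to the class whose mean is nearest in that class's Mahalanobis
    metric. Covariances are ridge-regularized when ill-conditioned.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MahalanobisQDA":
        self.classes_ = np.unique(y)
        self.means_ = []
        self.precisions_ = []
        p = X.shape[1]
        for c in self.classes_:
            Xc = X[y == c]
            mu = Xc.mean(axis=0)
            cov = np.cov(Xc, rowvar=False)
            cov = np.atleast_2d(cov)
            scale = max(np.trace(cov) / p, 1e-12)
            cov_r = cov + self.ridge * scale * np.eye(p)
            try:
                prec = np.linalg.inv(cov_r)
            except np.linalg.LinAlgError:
                cov_r = cov + 1e-3 * scale * np.eye(p)
                try:
                    prec = np.linalg.inv(cov_r)
                except np.linalg.LinAlgError as exc:
                    raise ConfigError(
                        f"singular covariance for class {c!r} "
                        "after ridge regularization") from exc
            self.means_.append(mu)
            self.precisions_.append(prec)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        d2 = np.empty((X.shape[0], len(self.classes_)))
        for j, (mu, prec) in enumerate(zip(self.means_, self.precisions_)):
            diff = X - mu
            d2[:, j] = np.einsum("ij,jk,ik->i", diff, prec, diff)
        return self.classes_[np.argmin(d2, axis=1)]


def make_classifier(spec: ClassifierSpec):
    """Instantiate the estimator behind a :class:`ClassifierSpec`."""
    from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                               QuadraticDiscriminantAnalysis)
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    n_classes = len(CONDITIONS)
    uniform = [1.0 / n_classes] * n_classes
    if spec.family == "KNN":
        return KNeighborsClassifier(n_neighbors=spec.k, metric="euclidean")
    if spec.family == "LSVM":
        return SVC(kernel="linear", C=spec.C)
    if spec.family == "GSVM":
        return SVC(kernel="rbf", C=spec.C, gamma=spec.gamma)
    if spec.family == "TREE":
        return DecisionTreeClassifier(criterion="gini",
                                      random_state=spec.random_state)
    if spec.family == "LDA":
        return LinearDiscriminantAnalysis(priors=uniform)
    if spec.family == "QDA":
        return QuadraticDiscriminantAnalysis(priors=uniform, reg_param=1e-6)
    if spec.family == "MQDA":
        return MahalanobisQDA()
    raise ConfigError(f"unknown family {spec.family!r}")


@dataclass
class CVResult:
    """Outcome of one LOSO evaluation."""

    classifier: ClassifierSpec
    feature_subset: Tuple[str, ...]
    subjects: np.ndarray
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    accuracy: float
    confusion: np.ndarray  # rows = true condition (canonical order)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=list(CONDITIONS),
                            columns=list(CONDITIONS))


def assemble_features(rows: Iterable[Mapping[str, object]]) -> pd.DataFrame:
    """Build the labelled feature table (one row per subject/trial/condition).

    Rows missing any of the 8 indices or carrying non-finite values are
    dropped with a logged reason; duplicate (subject, trial, condition)
    keys raise; an empty result raises.
    """
    kept, key_set = [], set()
    for row in rows:
        key = (row.get("subject_id"), row.get("trial"), row.get("condition"))
        if key in key_set:
            raise ConfigError(f"duplicate (subject, trial, condition) {key}")
        key_set.add(key)
        vals = [row.get(f) for f in FEATURE_NAMES]
        if any(v is None or not np.isfinite(v) for v in vals):
            logger.warning("dropping %s: missing or non-finite index", key)
            continue
        kept.append({"subject_id": key[0], "trial": int(key[1]),
                     "condition": key[2],
                     **{f: float(v) for f, v in zip(FEATURE_NAMES, vals)}})
    if not kept:
        raise ConfigError("no usable feature rows")
    df = pd.DataFrame(kept, columns=["subject_id", "trial", "condition",
                                     *FEATURE_NAMES])
    return df


def _standardize(train: np.ndarray, test: np.ndarray
                 ) -> Tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def fit_predict(spec: ClassifierSpec, train: pd.DataFrame, test: pd.DataFrame,
                subset: Sequence[str]) -> np.ndarray:
    """Standardize on the training fold, fit, and predict the test fold."""
    subset = tuple(subset)
    if not subset:
        raise ConfigError("feature subset must be non-empty")
    bad = [s for s in subset if s not in FEATURE_NAMES]
    if bad:
        raise ConfigError(f"unknown features {bad}")
    y_train = train["condition"].to_numpy()
    if set(y_train) != set(CONDITIONS):
        raise ConfigError("training fold must cover all 4 conditions")
    Xtr = train[list(subset)].to_numpy(dtype=float)
    Xte = test[list(subset)].to_numpy(dtype=float)
    Xtr, Xte = _standardize(Xtr, Xte)
    clf = make_classifier(spec)
    try:
        clf.fit(Xtr, y_train)
    except np.linalg.LinAlgError as exc:
        raise ConfigError(f"{spec.family}: singular class covariance "
                          f"({exc})") from exc
    return np.asarray(clf.predict(Xte))


def _confusion(true: np.ndarray, pred: np.ndarray) -> np.ndarray:
    idx = {c: i for i, c in enumerate(CONDITIONS)}
    M = np.zeros((len(CONDITIONS), len(CONDITIONS)), dtype=int)
    for t, p in zip(true, pred):
        M[idx[t], idx[p]] += 1
    return M


def loso_cv(samples: pd.DataFrame, spec: ClassifierSpec,
            subset: Sequence[str] = FEATURE_NAMES) -> CVResult:
    """Leave-one-subject-out cross-validation.

    One fold per subject: all of that subject's rows form the test set and
    every other subject's rows the training set. Accuracy and the 4x4
    confusion matrix are aggregated over folds.
    """
    subjects = samples["subject_id"].to_numpy()
    uniq = pd.unique(subjects)
    if uniq.size < 2:
        raise ConfigError("LOSO requires at least 2 subjects")
    preds = np.empty(len(samples), dtype=object)
    for sid in uniq:
        mask = subjects == sid
        train, test = samples[~mask], samples[mask]
        if set(train["condition"]) != set(CONDITIONS):
            raise ConfigError(
                f"training fold for held-out subject {sid!r} misses a condition")
        preds[mask] = fit_predict(spec, train, test, subset)
    true = samples["condition"].to_numpy()
    conf = _confusion(true, preds)
    acc = float(np.trace(conf) / conf.sum())
    return CVResult(classifier=spec, feature_subset=tuple(subset),
                    subjects=subjects, true_labels=true,
                    predicted_labels=preds.astype(str), accuracy=acc,
                    confusion=conf)


# -- fast numpy path used by the exhaustive subset search -------------------

def _loso_accuracy_fast(X: np.ndarray, y: np.ndarray, fold_masks: List[np.ndarray],
                        spec: ClassifierSpec, cols: Tuple[int, ...]) -> float:
    correct = 0
    Xs = X[:, cols]
    for mask in fold_masks:
        Xtr, Xte = Xs[~mask], Xs[mask]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        clf = make_classifier(spec)
        try:
            clf.fit((Xtr - mu) / sd, y[~mask])
        except np.linalg.LinAlgError as exc:
            raise ConfigError(f"{spec.family}: singular class covariance "
                              f"({exc})") from exc
        correct += int(np.sum(clf.predict((Xte - mu) / sd) == y[mask]))
    return correct / X.shape[0]


@dataclass(frozen=True)
class SubsetResult:
    feature_subset: Tuple[str, ...]
    accuracy: float


def subset_search(samples: pd.DataFrame, spec: ClassifierSpec
                  ) -> List[SubsetResult]:
    """Evaluate all 2^8 - 1 = 255 non-empty feature subsets under LOSO.

    Results are sorted by accuracy (descending), ties broken by fewer
    features then canonical name order. The winning subset is re-verified
    by an independent :func:`loso_cv` run; a mismatch raises.
    """
    missing = [f for f in FEATURE_NAMES if f not in samples.columns]
    if missing:
        raise ConfigError(f"feature table missing columns {missing}")
    X = samples[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = samples["condition"].to_numpy()
    subjects = samples["subject_id"].to_numpy()
    fold_masks = [subjects == sid for sid in pd.unique(subjects)]
    for m in fold_masks:
        if set(y[~m]) != set(CONDITIONS):
            raise ConfigError("a LOSO training fold misses a condition")

    results = []
    for r in range(1, len(FEATURE_NAMES) + 1):
        for cols in itertools.combinations(range(len(FEATURE_NAMES)), r):
            acc = _loso_accuracy_fast(X, y, fold_masks, spec, cols)
            results.append(SubsetResult(
                feature_subset=tuple(FEATURE_NAMES[i] for i in cols),
                accuracy=acc))
    results.sort(key=lambda s: (-s.accuracy, len(s.feature_subset),
                                tuple(FEATURE_NAMES.index(f)
                                      for f in s.feature_subset)))
    best = results[0]
    check = loso_cv(samples, spec, best.feature_subset)
    if abs(check.accuracy - best.accuracy) > 1e-12:
        raise ConfigError("subset search re-verification failed: "
                          f"{check.accuracy} != {best.accuracy}")
    return results


def temporal_generalization(samples: pd.DataFrame, spec: ClassifierSpec,
                            subset: Sequence[str] = FEATURE_NAMES
                            ) -> pd.DataFrame:
    """Train once on trial 1; score every later trial without retraining.

    Returns a table with one row per subsequent trial and its accuracy —
    the sustained-wakefulness generalization curve.
    """
    trials = sorted(samples["trial"].unique())
    if 1 not in trials:
        raise ConfigError("temporal generalization requires trial 1")
    later = [t for t in trials if t > 1]
    if not later:
        raise ConfigError("temporal generalization needs at least one later trial")
    train = samples[samples["trial"] == 1]
    rows = []
    for t in later:
        test = samples[samples["trial"] == t]
        preds = fit_predict(spec, train, test, subset)
        acc = float(np.mean(preds == test["condition"].to_numpy()))
        rows.append({"trial": t, "accuracy": acc,
                     "n_samples": len(test)})
    return pd.DataFrame(rows)
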