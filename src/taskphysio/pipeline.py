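"""End-to-end experiment orchestration: simulate -> extract -> compare ->
classify -> temporal generalization, as one reproducible, fully logged run.

``run_experiment`` writes to the output directory:

* ``features.csv`` — the labelled 8-index feature table;
* ``comparison.csv`` / ``comparison.txt`` — condition means ± SDs, ANOVA,
  Bonferroni markers (trial 1);
* ``best_subsets.csv`` — best exhaustive-search feature subset and LOSO
  accuracy per classifier;
* ``confusion_<family>.csv`` — row-normalized confusion matrix of each
  best model;
* ``temporal_accuracy.csv`` — per-trial accuracy of models trained on
  trial 1 only;
* ``config.yaml`` and ``run_log.txt`` — every parameter, seed, library
  version and stage timing needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (FEATURE_NAMES, ClassifierSpec, CVResult,
                       assemble_features, loso_cv, subset_search,
                       temporal_generalization)
from .core import CONDITIONS, ConfigError, SpectralBands, TaskPhysioError
from .eda import eda_indices
from .hrv import hrv_indices
from .simulate import (ConditionProfile, Recording, default_profiles,
                       iter_cohort)
from .stats import comparison_report

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one full experiment run.

    The defaults reproduce the emulated study design: 16 subjects, 12
    trials across the wakefulness protocol, 4 conditions per trial, ECG
    analyzed over 240 s at 256 Hz and EDA over 120 s at 8 Hz, seven
    classifiers with exhaustive subset search on trial 1, and the
    temporal-generalization evaluation for the two strongest families.
    Profiles shrink toward their grand mean by ``fatigue_factor`` from
    ``fatigue_trial`` on, emulating attenuated late-protocol reactivity.
    """

    n_subjects: int = 16
    n_trials: int = 12
    seed: int = 0
    ecg_window_s: float = 240.0
    eda_window_s: float = 120.0
    fs_ecg: float = 256.0
    fs_eda: float = 8.0
    fatigue_trial: Optional[int] = 8
    fatigue_factor: float = 0.6
    classifiers: Tuple[str, ...] = ("KNN", "LSVM", "GSVM", "TREE",
                                    "LDA", "QDA", "MQDA")
    temporal_classifiers: Tuple[str, ...] = ("KNN", "LSVM")
    search: bool = True
    bands: SpectralBands = field(default_factory=SpectralBands)
    profiles: Dict[str, ConditionProfile] = field(default_factory=default_profiles)
    outdir: str = "taskphysio_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = dataclasses.asdict(self.bands)
        d["profiles"] = {k: dataclasses.asdict(v)
                         for k, v in self.profiles.items()}
        return d

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "bands" in d:
            d["bands"] = SpectralBands(**{k: tuple(v)
                                          for k, v in d["bands"].items()})
        if "profiles" in d:
            d["profiles"] = {k: ConditionProfile(**v)
                             for k, v in d["profiles"].items()}
        for key in ("classifiers", "temporal_classifiers"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def extract_recording(rec: Recording, bands: SpectralBands | None = None
                      ) -> dict:
    """All 8 indices for one labelled recording (raises on quality failure)."""
    h = hrv_indices(rec.ecg, bands)
    e = eda_indices(rec.eda, bands)
    return {"subject_id": rec.subject_id, "trial": rec.trial,
            "condition": rec.condition,
            "SCL": e.SCL, "NS_SCRs": e.NS_SCRs, "EDASymp": e.EDASymp,
            "TVSymp": e.TVSymp, "HRVLF": h.HRVLF, "HRVLFn": h.HRVLFn,
            "HRVHF": h.HRVHF, "HRVHFn": h.HRVHFn}


def extract_features(recordings: Iterable[Recording],
                     bands: SpectralBands | None = None) -> pd.DataFrame:
    """Feature table for a recording collection; failed extractions are
    dropped with a logged reason."""
    rows = []
    for rec in recordings:
        try:
            rows.append(extract_recording(rec, bands))
        except TaskPhysioError as exc:
            logger.warning("dropping %s trial %d %s: %s", rec.subject_id,
                           rec.trial, rec.condition, exc)
    return assemble_features(rows)


def run_experiment(config: RunConfig) -> Dict[str, object]:
    """Execute the three analyses on a simulated cohort; write all artifacts.

    Returns a dict with the feature table, the comparison report, per-
    classifier best subset-search results, confusion matrices and the
    temporal-accuracy table. Any stage failure aborts with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s "
                                           "%(name)s: %(message)s"))
    root = logging.getLogger("taskphysio")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t0 = time.time()
    timings: Dict[str, float] = {}
    try:
        logger.info("taskphysio %s | numpy %s | python %s | seed %d",
                    __version__, np.__version__, platform.python_version(),
                    config.seed)
        config.to_yaml(outdir / "config.yaml")

        # stage 1+2: simulate and extract (streamed; raw signals are not
        # kept — use write_cohort()/the simulate subcommand for signal CSVs)
        stage = "simulate+extract"
        t_stage = time.time()
        cohort = iter_cohort(config.n_subjects, config.n_trials,
                             config.profiles, config.seed,
                             fatigue_trial=config.fatigue_trial,
                             fatigue_factor=config.fatigue_factor,
                             duration_ecg=config.ecg_window_s,
                             duration_eda=config.eda_window_s,
                             fs_ecg=config.fs_ecg, fs_eda=config.fs_eda)
        features = extract_features(cohort, config.bands)
        features.to_csv(outdir / "features.csv", index=False)
        timings[stage] = time.time() - t_stage
        logger.info("extracted %d feature rows in %.1f s", len(features),
                    timings[stage])

        # stage 3: repeated-measurements comparison on trial 1
        stage = "compare"
        t_stage = time.time()
        trial1 = features[features["trial"] == 1]
        report = comparison_report(trial1)
        report.table.to_csv(outdir / "comparison.csv", index=False)
        (outdir / "comparison.txt").write_text(report.to_text() + "\n")
        timings[stage] = time.time() - t_stage

        # stage 4: classification with exhaustive subset search on trial 1
        stage = "classify"
        t_stage = time.time()
        best_rows = []
        best_results: Dict[str, CVResult] = {}
        for family in config.classifiers:
            spec = ClassifierSpec(family=family,
                                  random_state=config.seed)
            try:
                if config.search:
                    ranked = subset_search(trial1, spec)
                    subset = ranked[0].feature_subset
                else:
                    subset = FEATURE_NAMES
                cv = loso_cv(trial1, spec, subset)
            except ConfigError as exc:
                # e.g. a quantized index constant within one class makes a
                # QDA fold covariance singular; report the rest
                logger.warning("excluding %s from the report: %s", family, exc)
                continue
            best_results[family] = cv
            best_rows.append({"model": family,
                              "accuracy_pct": round(100 * cv.accuracy, 1),
                              "indices": ", ".join(subset),
                              **{f"param_{k}": v
                                 for k, v in spec.metadata().items()
                                 if k != "family"}})
            frac = cv.confusion / cv.confusion.sum(axis=1, keepdims=True)
            pd.DataFrame(np.round(100 * frac, 1), index=list(CONDITIONS),
                         columns=list(CONDITIONS)).to_csv(
                outdir / f"confusion_{family}.csv")
        best_df = pd.DataFrame(best_rows)
        best_df.to_csv(outdir / "best_subsets.csv", index=False)
        timings[stage] = time.time() - t_stage
        logger.info("classification stage done in %.1f s", timings[stage])

        # stage 5: temporal generalization (train on trial 1 only)
        stage = "temporal"
        t_stage = time.time()
        temporal_frames = []
        if config.n_trials > 1:
            for family in config.temporal_classifiers:
                spec = ClassifierSpec(family=family, random_state=config.seed)
                subset = best_results[family].feature_subset
                tg = temporal_generalization(features, spec, subset)
                tg.insert(0, "model", family)
                temporal_frames.append(tg)
            temporal = pd.concat(temporal_frames, ignore_index=True)
        else:
            temporal = pd.DataFrame(columns=["model", "trial", "accuracy",
                                             "n_samples"])
        temporal.to_csv(outdir / "temporal_accuracy.csv", index=False)
        timings[stage] = time.time() - t_stage

        total = time.time() - t0
        logger.info("run complete in %.1f s (%s)", total,
                    ", ".join(f"{k}={v:.1f}s" for k, v in timings.items()))
        return {"features": features, "comparison": report,
                "best_subsets": best_df, "confusions": best_results,
                "temporal": temporal, "timings": timings,
                "total_seconds": total, "outdir": outdir}
    except TaskPhysioError as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise TaskPhysioError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
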