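"""Shared fixtures: small synthetic cohorts and feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import taskphysio as tp
from taskphysio.pipeline import extract_features

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")

#: small subject offsets used with the well-separated profiles so that
#: between-condition gaps dwarf within/between-subject variability
SMALL_OFFSET_SDS = {"mean_hr": 1.0, "lf_mod_amp": 0.004, "hf_mod_amp": 0.004,
                    "tonic_level": 0.15, "scr_rate": 0.2,
                    "scr_amp_log_mean": 0.05}


@pytest.fixture(scope="session")
def separable_features() -> pd.DataFrame:
    """Feature table of a 16-subject, 1-trial cohort with well-separated
    condition profiles (the separability control)."""
    cohort = tp.iter_cohort(16, 1, tp.well_separated_profiles(), seed=7,
                            offset_sds=SMALL_OFFSET_SDS)
    return extract_features(cohort)


def gaussian_feature_table(n_subjects: int, n_trials: int, seed: int,
                           means: dict[str, np.ndarray] | None = None,
                           sd: float = 1.0) -> pd.DataFrame:
    """Synthetic labelled feature table drawn directly in feature space
    (no signal simulation): one Gaussian blob per condition."""
    rng = np.random.default_rng(seed)
    if means is None:
        means = {c: rng.normal(0, 3, size=len(tp.FEATURE_NAMES))
                 for c in tp.CONDITIONS}
    rows = []
    for s in range(n_subjects):
        for t in range(1, n_trials + 1):
            for c in tp.CONDITIONS:
                x = rng.normal(means[c], sd)
                rows.append({"subject_id": f"S{s:02d}", "trial": t,
                             "condition": c,
                             **dict(zip(tp.FEATURE_NAMES, x))})
    return tp.assemble_features(rows)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
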