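"""Simulate a small labelled cohort and inspect its structure.

Generates ECG + skin-conductance recordings for 2 subjects x 1 trial x the
four conditions (baseline, psychomotor vigilance, n-back, ship search) and
writes the cohort directory (signal CSVs, truth sidecars, manifest).
"""

import tempfile
from pathlib import Path

import taskphysio as tp

cohort = tp.generate_cohort(n_subjects=2, n_trials=1,
                            profiles=tp.default_profiles(), seed=42)
outdir = Path(tempfile.mkdtemp()) / "cohort"
tp.write_cohort(cohort, outdir)

print(f"{len(cohort)} recordings written to {outdir}")
for rec in cohort[:4]:
    truth = rec.truth_eda
    print(f"  {rec.subject_id} trial {rec.trial} {rec.condition:5s}: "
          f"ECG {rec.ecg.duration:.0f} s @ {rec.ecg.fs:.0f} Hz, "
          f"EDA {rec.eda.duration:.0f} s @ {rec.eda.fs:.0f} Hz, "
          f"{truth.scr_event_times.size} true SCR events")

# Each condition has its own generative profile: the tonic skin-conductance
# level and SCR rate rise under task load, and the LF/HF cardiac modulation
# depths differ, so the extracted indices separate the conditions.
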