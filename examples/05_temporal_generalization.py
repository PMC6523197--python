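"""Temporal generalization: train on the first trial, test on later ones.

Simulates a 6-subject cohort over 8 trials with the separation-attenuation
knob engaged from trial 6 (emulating attenuated autonomic reactivity late in
a sustained-wakefulness protocol), trains a KNN model on trial 1 only, and
scores every later trial without retraining.
"""

import taskphysio as tp
from taskphysio.pipeline import extract_features

cohort = tp.iter_cohort(6, 8, tp.default_profiles(), seed=11,
                        fatigue_trial=6, fatigue_factor=0.5)
features = extract_features(cohort)

tg = tp.temporal_generalization(features, tp.ClassifierSpec("KNN"))
print("trial  accuracy")
for _, row in tg.iterrows():
    marker = "  <- attenuated separation" if row["trial"] >= 6 else ""
    print(f"  {int(row['trial']):2d}    {100 * row['accuracy']:5.1f}%{marker}")

# Accuracy holds near its trial-2 level while the condition profiles are
# stationary and drops once the between-condition separation is attenuated —
# the pattern reported for sustained-wakefulness protocols.
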