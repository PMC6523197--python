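"""Repeated-measurements comparison of the indices across conditions.

Extracts the feature table of an 8-subject cohort and prints the
summary-table-style report: condition means ± SDs with ANOVA and
Bonferroni-corrected paired-test markers (* vs baseline, † vs PVT,
‡ vs n-back).
"""

import taskphysio as tp
from taskphysio.pipeline import extract_features

cohort = tp.iter_cohort(8, 1, tp.default_profiles(), seed=3)
features = extract_features(cohort)
report = tp.comparison_report(features)
print(report.to_text())

# A marker on a condition's cell means the paired difference to the marked
# reference survived the alpha/6 Bonferroni threshold; with only 8 subjects
# only the largest separations (e.g. tonic level vs baseline) reach it.
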