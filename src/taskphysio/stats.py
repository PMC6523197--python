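"""Repeated-measurements comparison of the autonomic indices across tasks.

Per index: Kolmogorov-Smirnov normality screening, a one-way ANOVA across
the four conditions, and all six pairwise paired t-tests with Bonferroni
correction (α/6), rendered as a summary table of condition means ± SDs with
significance markers ('*' vs baseline, '†' vs PVT, '‡' vs n-back).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as ss

from .core import CONDITIONS, ConfigError

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05

_lilliefors_warned = False

#: marker symbol for a significant difference vs. each reference condition
MARKERS: Dict[str, str] = {"BL": "*", "PVT": "†", "NBACK": "‡"}


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    passed: bool
    diagnostic: Optional[str] = None


def ks_normality(values: Sequence[float], alpha: float = ALPHA_DEFAULT
                 ) -> NormalityResult:
    """One-sample KS test of standardized values against the standard normal.

    Note: standardizing by the sample mean/SD before a one-sample KS test is
    anti-conservative (the Lilliefors situation); a warning is logged, and
    the test is applied as stated all the same.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ConfigError(f"need at least 8 values for the KS screen, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        return NormalityResult(statistic=float("nan"), p_value=0.0,
                               passed=False,
                               diagnostic="zero variance: all values identical")
    global _lilliefors_warned
    if not _lilliefors_warned:
        logger.warning("KS normality with estimated mean/SD is "
                       "anti-conservative (Lilliefors); interpret marginal "
                       "p-values with care")
        _lilliefors_warned = True
    z = (x - x.mean()) / sd
    stat, p = ss.kstest(z, "norm")
    return NormalityResult(statistic=float(stat), p_value=float(p),
                           passed=bool(p >= alpha))


def anova_conditions(groups: Mapping[str, Sequence[float]]
                     ) -> Tuple[float, float]:
    """Classical one-way ANOVA F and p across condition groups.

    Degenerate contract: if every group is the same constant (zero between-
    and within-group variance) the F statistic is reported as 0 with p = 1.
    """
    if len(groups) < 2:
        raise ConfigError("ANOVA needs at least 2 groups")
    arrays = []
    for name, vals in groups.items():
        g = np.asarray(vals, dtype=float)
        if g.size < 2:
            raise ConfigError(f"group {name!r} has fewer than 2 values")
        arrays.append(g)
    allv = np.concatenate(arrays)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    f, p = ss.f_oneway(*arrays)
    return float(f), float(p)


@dataclass(frozen=True)
class PairwiseResult:
    """Bonferroni-corrected paired comparisons for one index."""

    p_values: Dict[Tuple[str, str], float]
    significant: Dict[Tuple[str, str], bool]
    markers: Dict[str, str]
    alpha: float
    n_comparisons: int


def pairwise_bonferroni(groups: Mapping[str, Sequence[float]],
                        alpha: float = ALPHA_DEFAULT) -> PairwiseResult:
    """All 6 pairwise paired t-tests with Bonferroni correction.

    Values must be aligned by subject across conditions (the repeated-
    measures design); a pair is significant iff its p-value is below
    ``alpha / 6``. Markers follow the summary-table convention: each
    condition is flagged with the symbol of every earlier condition it
    differs from.
    """
    sizes = {c: len(groups[c]) for c in CONDITIONS if c in groups}
    if set(sizes) != set(CONDITIONS):
        raise ConfigError("pairwise comparison needs all 4 condition groups")
    if len(set(sizes.values())) != 1:
        raise ConfigError(
            f"groups must be subject-aligned (equal sizes), got {sizes}")
    pairs = list(combinations(CONDITIONS, 2))
    n_comp = len(pairs)
    p_values: Dict[Tuple[str, str], float] = {}
    significant: Dict[Tuple[str, str], bool] = {}
    for a, b in pairs:
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        if np.ptp(x - y) == 0:  # identical paired samples -> no evidence
            p = 1.0
        else:
            p = float(ss.ttest_rel(x, y).pvalue)
        p_values[(a, b)] = p
        significant[(a, b)] = p < alpha / n_comp
    markers = {}
    for cond in CONDITIONS:
        syms = ""
        for ref, sym in MARKERS.items():
            if ref == cond:
                continue
            key = (ref, cond) if (ref, cond) in significant else (cond, ref)
            if CONDITIONS.index(ref) < CONDITIONS.index(cond) and significant[key]:
                syms += sym
        markers[cond] = syms
    return PairwiseResult(p_values=p_values, significant=significant,
                          markers=markers, alpha=alpha, n_comparisons=n_comp)


@dataclass
class ComparisonReport:
    """Per-index condition summaries, ANOVA and pairwise markers."""

    table: pd.DataFrame          # one row per index
    alpha: float
    n_comparisons: int

    def to_text(self) -> str:
        """Render a summary-table-style text block (mean ± SD with markers)."""
        lines = ["Index".ljust(10) + "".join(c.ljust(18) for c in CONDITIONS)
                 + "ANOVA F (p)"]
        for _, row in self.table.iterrows():
            cells = []
            for c in CONDITIONS:
                cells.append(f"{row[f'{c}_mean']:.3g} ± {row[f'{c}_sd']:.2g}"
                             f"{row[f'{c}_markers']}".ljust(18))
            lines.append(row["index"].ljust(10) + "".join(cells)
                         + f"{row['anova_F']:.3g} ({row['anova_p']:.2g})")
        lines.append(f"markers: * vs BL, † vs PVT, ‡ vs n-back "
                     f"(paired t, Bonferroni x{self.n_comparisons}, "
                     f"alpha={self.alpha})")
        return "\n".join(lines)


def comparison_report(features: pd.DataFrame,
                      index_names: Sequence[str] | None = None,
                      alpha: float = ALPHA_DEFAULT) -> ComparisonReport:
    """Build the repeated-measurements comparison across the four conditions.

    ``features`` is a feature table (one row per subject/trial/condition);
    only trial-1 rows should be passed for the first-trial comparison. Rows
    are aligned by subject within each condition before the paired stage.
    """
    from .classify import FEATURE_NAMES

    names = list(index_names or FEATURE_NAMES)
    rows = []
    for name in names:
        groups: Dict[str, np.ndarray] = {}
        pivot = features.pivot_table(index="subject_id", columns="condition",
                                     values=name, aggfunc="mean")
        if pivot.isna().any().any():
            raise ConfigError(
                f"index {name!r}: subjects are not matched across conditions")
        for cond in CONDITIONS:
            groups[cond] = pivot[cond].to_numpy()
        norm = {c: ks_normality(groups[c]) if len(groups[c]) >= 8 else None
                for c in CONDITIONS}
        F, p = anova_conditions(groups)
        pw = pairwise_bonferroni(groups, alpha=alpha)
        row = {"index": name, "anova_F": F, "anova_p": p}
        for cond in CONDITIONS:
            row[f"{cond}_mean"] = float(np.mean(groups[cond]))
            row[f"{cond}_sd"] = float(np.std(groups[cond], ddof=1))
            row[f"{cond}_n"] = int(len(groups[cond]))
            row[f"{cond}_markers"] = pw.markers[cond]
            nr = norm[cond]
            row[f"{cond}_ks_pass"] = (bool(nr.passed) if nr is not None
                                      else None)
        rows.append(row)
    table = pd.DataFrame(rows)
    return ComparisonReport(table=table, alpha=alpha,
                            n_comparisons=len(list(combinations(CONDITIONS, 2))))
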