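"""Candidate-biomarker selection and group-comparison statistics.

A feature qualifies as a candidate when it is detected (raw count >= 1) in
strictly more than 80 % of the pCR group and its median normalized value
strictly exceeds 100 in both groups (the median scope is configurable to
"either group", since the criterion sentence is readable both ways).
Continuous comparisons use the two-sided Mann-Whitney U test (exact
enumeration at small n without ties), categorical ones the Pearson
chi-square test without continuity correction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .quantify import ExpressionMatrix

PCR = "pCR"
NON_PCR = "non-pCR"

#: Largest per-group size at which the Mann-Whitney null is enumerated
#: exactly (ties force the tie-corrected normal approximation instead).
EXACT_MW_MAX_N = 8


@dataclass
class LabeledMatrix:
    """Expression matrix plus a pCR / non-pCR label per sample."""

    matrix: ExpressionMatrix
    labels: pd.Series  # sample_id -> "pCR" | "non-pCR"

    def __post_init__(self):
        self.labels = pd.Series(self.labels)
        missing = set(self.matrix.sample_ids) - set(self.labels.index)
        if missing:
            raise ValueError(f"unlabeled samples: {sorted(missing)[:5]}")
        vals = set(self.labels.loc[self.matrix.sample_ids])
        if vals != {PCR, NON_PCR}:
            raise ValueError(f"need both classes present, got labels {sorted(vals)}")

    def group_index(self, group: str) -> pd.Index:
        lab = self.labels.loc[self.matrix.sample_ids]
        return lab.index[lab == group]


@dataclass
class CandidateCriteria:
    detect_fraction: float = 0.8  # strict >
    median_floor: float = 100.0  # strict >
    median_scope: str = "both_groups"  # or "either_group"

    def __post_init__(self):
        # 0 is allowed as a degenerate "no detection requirement" setting
        if not 0 <= self.detect_fraction <= 1:
            raise ValueError("detect_fraction must be in [0, 1]")
        if self.median_floor < 0:
            raise ValueError("median_floor must be >= 0")
        if self.median_scope not in ("both_groups", "either_group"):
            raise ValueError("median_scope must be 'both_groups' or 'either_group'")


def detection_fraction(raw_counts: Sequence[float]) -> float:
    """Fraction of samples in which the feature is detected (count >= 1)."""
    arr = np.asarray(raw_counts, dtype=float)
    if arr.size == 0:
        raise ValueError("empty group")
    return float(np.mean(arr >= 1))


def select_candidates(
    lm: LabeledMatrix, crit: CandidateCriteria | None = None
) -> list[str]:
    """Features passing the detection and median criteria, ordered by
    descending pCR-group median (ties lexicographic)."""
    crit = crit or CandidateCriteria()
    pcr_idx = lm.group_index(PCR)
    non_idx = lm.group_index(NON_PCR)
    kept: list[tuple[float, str]] = []
    for feat in lm.matrix.feature_ids:
        det = detection_fraction(lm.matrix.raw.loc[pcr_idx, feat])
        # strict ">"; a threshold of exactly 0 disables the requirement
        if crit.detect_fraction > 0 and not det > crit.detect_fraction:
            continue
        med_p = float(lm.matrix.values.loc[pcr_idx, feat].median())
        med_n = float(lm.matrix.values.loc[non_idx, feat].median())
        if crit.median_scope == "both_groups":
            ok = med_p > crit.median_floor and med_n > crit.median_floor
        else:
            ok = med_p > crit.median_floor or med_n > crit.median_floor
        if ok:
            kept.append((med_p, feat))
    kept.sort(key=lambda t: (-t[0], t[1]))
    return [f for _m, f in kept]


def compare_feature(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney p-value plus the two group medians.

    Exact null enumeration when min(n) <= 8 and the pooled sample has no
    ties; tie- and continuity-corrected normal approximation otherwise.
    A U statistic exactly at its null mean is reported as p = 1 (the
    two-sided evidence is nil; the continuity shift would otherwise push
    a perfectly balanced comparison below 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= EXACT_MW_MAX_N and not has_ties:
        res = st.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = st.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        if float(res.statistic) == len(x) * len(y) / 2:
            return 1.0, float(np.median(x)), float(np.median(y))
    return float(res.pvalue), float(np.median(x)), float(np.median(y))


def compare_clinical(values, labels, kind: str) -> float:
    """Group-comparison p-value for one clinical factor.

    ``kind="continuous"``: Mann-Whitney on the two label groups.
    ``kind="categorical"``: Pearson chi-square without continuity
    correction on the r x 2 contingency table of value by label.
    """
    values = pd.Series(list(values))
    labels = pd.Series(list(labels))
    if kind == "continuous":
        groups = [values[labels == g].to_numpy(dtype=float) for g in sorted(labels.unique())]
        if len(groups) != 2:
            raise ValueError("continuous comparison needs exactly 2 label groups")
        p, _mx, _my = compare_feature(groups[0], groups[1])
        return p
    if kind != "categorical":
        raise ValueError("kind must be 'continuous' or 'categorical'")
    table = pd.crosstab(values, labels)
    if table.shape[1] != 2:
        raise ValueError("categorical comparison needs exactly 2 label groups")
    if table.shape[0] < 2:
        raise ValueError("degenerate contingency table (factor has a single level)")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table (empty row or column)")
    stat, p, _dof, _exp = st.chi2_contingency(table.to_numpy(), correction=False)
    return float(p)


def fisher_exact_p(table_2x2) -> float:
    """Fisher exact two-sided p for a 2x2 table (alternative to chi-square)."""
    _or, p = st.fisher_exact(np.asarray(table_2x2))
    return float(p)


@dataclass
class FeatureComparison:
    feature_id: str
    detection_pcr: float
    median_pcr: float
    median_nonpcr: float
    p_value: float


def candidate_table(lm: LabeledMatrix, crit: CandidateCriteria | None = None) -> pd.DataFrame:
    """Per-candidate summary: detection fraction, group medians, MW p."""
    pcr_idx = lm.group_index(PCR)
    non_idx = lm.group_index(NON_PCR)
    rows = []
    for feat in select_candidates(lm, crit):
        x = lm.matrix.values.loc[pcr_idx, feat].to_numpy()
        y = lm.matrix.values.loc[non_idx, feat].to_numpy()
        p, mx, my = compare_feature(x, y)
        rows.append(
            FeatureComparison(
                feature_id=feat,
                detection_pcr=detection_fraction(lm.matrix.raw.loc[pcr_idx, feat]),
                median_pcr=mx,
                median_nonpcr=my,
                p_value=p,
            ).__dict__
        )
    return pd.DataFrame(rows, columns=["feature_id", "detection_pcr", "median_pcr", "median_nonpcr", "p_value"]).set_index("feature_id")
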