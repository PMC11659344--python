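"""Classification metrics, ROC/AUC with Youden cutoff, and 2x2 odds ratios.

Scores are oriented so that higher means more likely pCR.  AUC uses the
Mann-Whitney pair-counting equivalence (ties count one half), computed via
mid-ranks; the ROC polyline enumerates every distinct score threshold.
Odds ratios come with Wald 95 % intervals; a zero cell yields an explicit
non-estimable result rather than a silent continuity correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

Z95 = 1.959963984540054


@dataclass
class MetricsReport:
    accuracy: float
    precision: float  # NaN when no positives are predicted
    recall: float
    f_measure: float  # NaN when precision or recall is undefined/zero sum
    auc: float
    threshold: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def classification_metrics(scores, labels, threshold: float) -> MetricsReport:
    """Confusion-matrix metrics with positive = score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    accuracy = (tp + tn) / len(y)
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = tp / (tp + fn)
    if np.isnan(precision) or (precision + recall) == 0:
        f_measure = float("nan")
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=float(accuracy),
        precision=float(precision),
        recall=float(recall),
        f_measure=float(f_measure),
        auc=roc_auc(scores, y).auc,
        threshold=float(threshold),
    )


@dataclass
class ROCResult:
    points: pd.DataFrame  # columns fpr, tpr, threshold (thresholds descending)
    auc: float
    youden_cutoff: float
    sensitivity: float  # at the Youden cutoff
    specificity: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve, rank-based AUC and the Youden-index operating cutoff.

    AUC = P(score_case > score_control) + 0.5 P(tie), computed from
    mid-ranks.  Cutoff = argmax(sensitivity + specificity - 1) over the
    distinct scores, ties resolved toward the lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes")

    ranks = rankdata(scores)
    auc = (np.sum(ranks[y == 1]) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    thresholds = np.unique(scores)[::-1]
    tpr = np.array([np.mean(scores[y == 1] >= t) for t in thresholds])
    fpr = np.array([np.mean(scores[y == 0] >= t) for t in thresholds])
    points = pd.DataFrame(
        {
            "fpr": np.concatenate([[0.0], fpr]),
            "tpr": np.concatenate([[0.0], tpr]),
            "threshold": np.concatenate([[np.inf], thresholds]),
        }
    )

    youden = tpr - fpr
    best = np.max(youden)
    # ties -> lower cutoff; thresholds are descending so take the last argmax
    idx = int(np.max(np.nonzero(youden == best)[0]))
    return ROCResult(
        points=points,
        auc=float(auc),
        youden_cutoff=float(thresholds[idx]),
        sensitivity=float(tpr[idx]),
        specificity=float(1 - fpr[idx]),
    )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with "case" rows and "exposed" columns semantics:
    (exposed_case, exposed_noncase, unexposed_case, unexposed_noncase)."""

    exposed_case: int
    exposed_noncase: int
    unexposed_case: int
    unexposed_noncase: int

    def __post_init__(self):
        vals = (self.exposed_case, self.exposed_noncase, self.unexposed_case, self.unexposed_noncase)
        if any(v < 0 for v in vals):
            raise ValueError("counts must be >= 0")
        if sum(vals) == 0:
            raise ValueError("table total must be > 0")


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    estimable: bool = True


def odds_ratio_wald(table: ContingencyTable2x2) -> OddsRatioResult:
    """Cross-product odds ratio with Wald 95 % CI.

    OR = (a d)/(b c) for a=exposed_case, b=exposed_noncase, c=unexposed_case,
    d=unexposed_noncase; CI = exp(ln OR +/- 1.96 sqrt(1/a+1/b+1/c+1/d)).
    Any zero cell makes the result non-estimable (all values NaN).
    """
    a, b, c, d = (
        table.exposed_case,
        table.exposed_noncase,
        table.unexposed_case,
        table.unexposed_noncase,
    )
    if 0 in (a, b, c, d):
        return OddsRatioResult(float("nan"), float("nan"), float("nan"), estimable=False)
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        odds_ratio=float(or_),
        ci_low=float(or_ * np.exp(-Z95 * se)),
        ci_high=float(or_ * np.exp(Z95 * se)),
    )
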