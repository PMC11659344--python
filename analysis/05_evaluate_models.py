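#!/usr/bin/env python
"""Evaluate the three fitted scores on the cohort.

Scores every sample with each model's linear predictor, reports ROC AUC,
the Youden operating cutoff with its sensitivity/specificity, and
confusion-matrix metrics at that cutoff; also recomputes the univariate
odds ratios for the reported clinical 2x2 counts as a worked example.
Writes results/evaluation/metrics.json and scores.tsv.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent))

import numpy as np
import pandas as pd

from srnapcr.evaluation import (
    ContingencyTable2x2,
    classification_metrics,
    odds_ratio_wald,
    roc_auc,
)
from srnapcr.models import clinical_design
from srnapcr.pipeline import stage_seed
from srnapcr.published import CLINICAL_2X2
from srnapcr.quantify import ExpressionMatrix
from srnapcr.synthetic import CohortConfig, simulate_cohort

SEED = 7
ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "evaluation"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(ROOT / "results/cohort/counts.tsv", sep="\t", index_col=0)
    clin = pd.read_csv(ROOT / "results/cohort/clinical.csv", index_col=0)
    matrix = ExpressionMatrix.from_counts(counts)
    samples = simulate_cohort(CohortConfig(seed=stage_seed(SEED, "simulate")))
    records = [s.clinical for s in samples]
    y = (clin["group"] == "pCR").to_numpy(dtype=float)

    metrics = {}
    scores_df = pd.DataFrame(index=clin.index)
    for tag in ("cf", "sr", "c"):
        payload = json.loads((ROOT / f"results/models/model_{tag}.json").read_text())
        coeffs = payload["coefficients"] if tag != "cf" else payload
        terms = list(coeffs["coefficients"])
        design = pd.DataFrame(index=range(len(records)))
        for t in terms:
            if t in matrix.feature_ids:
                design[t] = matrix.values[t].to_numpy()
            else:
                design[t] = clinical_design(records, [t])[t].to_numpy()
        scores = design.to_numpy() @ np.array([coeffs["coefficients"][t] for t in terms])
        scores = scores + coeffs["intercept"]
        scores_df[f"{tag}_pm"] = scores
        roc = roc_auc(scores, y)
        rep = classification_metrics(scores, y, roc.youden_cutoff)
        metrics[f"{tag}_pm"] = {
            "auc": round(roc.auc, 3),
            "youden_cutoff": round(roc.youden_cutoff, 3),
            "sensitivity": round(roc.sensitivity, 3),
            "specificity": round(roc.specificity, 3),
            "accuracy": round(rep.accuracy, 3),
            "precision": round(rep.precision, 3),
            "recall": round(rep.recall, 3),
            "f_measure": round(rep.f_measure, 3),
        }
        print(f"{tag.upper()}-PM: " + ", ".join(f"{k}={v}" for k, v in metrics[f"{tag}_pm"].items()))

    ors = {}
    for factor, table in CLINICAL_2X2.items():
        res = odds_ratio_wald(ContingencyTable2x2(*table))
        ors[factor] = (
            None
            if not res.estimable
            else {"or": round(res.odds_ratio, 2), "ci": [round(res.ci_low, 2), round(res.ci_high, 2)]}
        )
    print("univariate ORs from the reported clinical 2x2 counts:")
    for k, v in ors.items():
        print(f"  {k:16s} {v}")

    scores_df["group"] = clin["group"]
    scores_df.to_csv(OUT / "scores.tsv", sep="\t")
    (OUT / "metrics.json").write_text(
        json.dumps({"models": metrics, "clinical_univariate_or": ors}, indent=2, sort_keys=True)
    )
    print(f"wrote evaluation outputs to {OUT}")


if __name__ == "__main__":
    main()
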