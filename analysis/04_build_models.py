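#!/usr/bin/env python
"""Build the three predictive scores on the simulated cohort.

CF-PM: logistic model over clinical factors passing the p<0.1 screen.
SR-PM: candidates ranked by cross-validated univariate OR (per 100
normalized units), nested top-1..3 models compared by mean CV AUC, best
refit on all data.  C-PM: the same nesting with the screened clinical
terms included.  Writes model_{cf,sr,c}.json under results/models/.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent))

import numpy as np
import pandas as pd

from srnapcr.models import (
    CVConfig,
    build_nested_models,
    clinical_design,
    fit_logistic,
    rank_features_by_cv_or,
    screen_clinical,
)
from srnapcr.pipeline import stage_seed
from srnapcr.quantify import ExpressionMatrix
from srnapcr.selection import LabeledMatrix, select_candidates
from srnapcr.synthetic import CohortConfig, simulate_cohort

SEED = 7
ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "models"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(COHORT / "counts.tsv", sep="\t", index_col=0)
    clin = pd.read_csv(COHORT / "clinical.csv", index_col=0)
    lm = LabeledMatrix(matrix=ExpressionMatrix.from_counts(counts), labels=clin["group"])
    # clinical records are regenerated from the same stage seed, so they
    # match clinical.csv row for row
    samples = simulate_cohort(CohortConfig(seed=stage_seed(SEED, "simulate")))
    records = [s.clinical for s in samples]
    y = (clin["group"] == "pCR").to_numpy(dtype=float)
    cv = CVConfig(seed=stage_seed(SEED, "folds"))

    screened = screen_clinical(records)
    print(f"clinical factors passing p<0.1 screen: {screened}")
    cd = clinical_design(records, screened)
    cf = fit_logistic(cd, y, firth=True)
    (OUT / "model_cf.json").write_text(json.dumps(cf.to_dict(), indent=2, sort_keys=True))

    candidates = select_candidates(lm)
    ranked = rank_features_by_cv_or(lm, candidates, cv)
    print("cross-validated univariate ORs (per 100 units, strongest first):")
    for feat, or_ in ranked:
        print(f"  {feat:28s} {or_:6.3f}")
    ranked_names = [f for f, _ in ranked]

    sr = build_nested_models(lm, ranked_names, None, max_k=3, cv=cv)
    c = build_nested_models(lm, ranked_names, cd, max_k=3, cv=cv)
    for tag, res in (("sr", sr), ("c", c)):
        payload = {
            "best_k": res.best_k,
            "coefficients": res.final_coefficients.to_dict(),
            "cv_metrics": [e.cv_metrics.to_dict() | {"k": e.k} for e in res.entries],
        }
        (OUT / f"model_{tag}.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        aucs = {e.k: round(e.cv_metrics.auc, 3) for e in res.entries}
        print(f"{tag.upper()}-PM: CV AUC by k = {aucs}, best k = {res.best_k}")
    print(f"wrote model_cf/sr/c.json to {OUT}")


if __name__ == "__main__":
    main()
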