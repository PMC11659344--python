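#!/usr/bin/env python
"""Prognosis analysis on the simulated cohort.

Kaplan-Meier curves with log-rank tests for recurrence-free and overall
survival, stratified (a) by pCR status and (b) by high/low combined score
at its Youden cutoff, plus Cox models for each stratification.  Writes
results/survival/summary.json and KM curve tables.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent))

import numpy as np
import pandas as pd

from srnapcr.survival import cox_fit, km_logrank

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "survival"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    clin = pd.read_csv(ROOT / "results/cohort/clinical.csv", index_col=0)
    scores = pd.read_csv(ROOT / "results/evaluation/scores.tsv", sep="\t", index_col=0)
    metrics = json.loads((ROOT / "results/evaluation/metrics.json").read_text())
    cutoff = metrics["models"]["c_pm"]["youden_cutoff"]

    summary = {}
    strata = {
        "pcr": np.where(clin["group"] == "pCR", "pCR", "non-pCR"),
        "cpm": np.where(scores["c_pm"] >= cutoff, "C-PM high", "C-PM low"),
    }
    for endpoint in ("rfs", "os"):
        times = clin[f"{endpoint}_time"].to_numpy()
        events = clin[f"{endpoint}_event"].astype(int).to_numpy()
        for name, groups in strata.items():
            fit = km_logrank(times, events, groups)
            indicator = (groups == ("pCR" if name == "pcr" else "C-PM high")).astype(float)
            cx = cox_fit(times, events, pd.DataFrame({name: indicator}))
            hr, lo, hi = cx.hazard_ratios[name]
            summary[f"{endpoint}_{name}"] = {
                "logrank_p": round(fit.logrank_p, 5),
                "hr": round(hr, 2),
                "hr_ci": [round(lo, 2), round(hi, 2)],
                "hr_p": round(cx.hr_p_values[name], 5),
            }
            print(
                f"{endpoint.upper()} by {name}: log-rank p={fit.logrank_p:.4f}, "
                f"HR={hr:.2f} ({lo:.2f}-{hi:.2f})"
            )
            for g, curve in fit.km.items():
                pd.DataFrame({"time": curve.times, "survival": curve.survival}).to_csv(
                    OUT / f"km_{endpoint}_{name}_{g.replace(' ', '_').replace('/', '_')}.tsv",
                    sep="\t",
                    index=False,
                )
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    print(f"wrote survival outputs to {OUT}")


if __name__ == "__main__":
    main()
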