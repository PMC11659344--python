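#!/usr/bin/env python
"""Simulate the study-sized cohort (30 pCR / 69 non-pCR).

Writes the per-sample count table, clinical table, planted-truth table and
the toy reference files under results/cohort/.  The cohort's group medians
for the three marker features target the reported group medians, so the
downstream scripts see data with the effect structure the analysis expects.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent))

from srnapcr.pipeline import stage_seed
from srnapcr.synthetic import (
    CohortConfig,
    clinical_frame,
    counts_frame,
    make_reference_set,
    simulate_cohort,
    truth_frame,
)

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = CohortConfig(seed=stage_seed(SEED, "simulate"))
    samples = simulate_cohort(cfg)
    clin = clinical_frame(samples)
    counts = counts_frame(samples)
    clin.to_csv(OUT / "clinical.csv")
    counts.to_csv(OUT / "counts.tsv", sep="\t")
    truth_frame(cfg).to_csv(OUT / "truth.csv")

    refs = make_reference_set(SEED)
    refs.mirna_fasta(OUT / "mirna.fa")
    refs.trna_fasta(OUT / "trna.fa")
    refs.loops_tsv(OUT / "trna_loops.tsv")

    n_pcr = int((clin["group"] == "pCR").sum())
    print(f"simulated {len(samples)} samples ({n_pcr} pCR / {len(samples) - n_pcr} non-pCR)")
    pcr = clin.index[clin["group"] == "pCR"]
    for feat in ("let-7b-5p|3d:T|3a:CTC", "miR-93-5p|3d:|3a:TTTG", "tRNA-Gly-CCC/GCC"):
        print(f"  pCR median raw count  {feat:28s} {counts.loc[pcr, feat].median():8.1f}")
    print(f"wrote cohort tables and toy references to {OUT}")


if __name__ == "__main__":
    main()
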