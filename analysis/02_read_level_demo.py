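#!/usr/bin/env python
"""Drive the quantification stage from raw reads.

Emits FASTQ for a small-depth cohort (no background bulk, ~1,000 reads per
sample), runs the full per-library pipeline — collapse, isomiR calling,
hemolysis exclusion, tRNA-fragment classification/grouping, normalization
to 1e6 — and verifies that at zero sequencing noise the planted counts come
back exactly.  Writes the matrix and QC under results/readlevel/.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent))

import pandas as pd

from srnapcr.quantify import ExpressionMatrix, quantify_library
from srnapcr.synthetic import (
    CohortConfig,
    emit_reads,
    make_reference_set,
    read_scale_feature_plans,
    simulate_cohort,
    write_fastq,
)

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "readlevel"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    refs = make_reference_set(SEED)
    cfg = CohortConfig(n_pcr=3, n_nonpcr=3, features=read_scale_feature_plans(), seed=SEED)
    samples = simulate_cohort(cfg)

    libs = {}
    exact = 0
    for sample in samples:
        records = emit_reads(sample, refs, error_rate=0.0, seed=SEED + 1)
        write_fastq(records, OUT / f"{sample.sample_id}.fastq")
        q = quantify_library([str(r.seq) for r in records], refs)
        libs[sample.sample_id] = q
        exact += q.raw == {k: v for k, v in sample.feature_counts.items() if v > 0}

    em = ExpressionMatrix.from_libraries(libs)
    em.to_tsv(OUT / "matrix.tsv")
    qc = pd.DataFrame(
        {s: {k: v for k, v in q.qc.items() if k != "tsrna_members"} for s, q in libs.items()}
    ).T
    qc.rename_axis("sample_id").to_csv(OUT / "qc.tsv", sep="\t")

    print(f"quantified {len(libs)} read-level libraries ({qc['input_reads'].sum()} reads)")
    print(f"zero-noise round trip exact for {exact}/{len(samples)} samples")
    print(f"normalized row sums: {em.values.sum(axis=1).round(6).unique().tolist()}")
    print(f"wrote matrix and QC to {OUT}")


if __name__ == "__main__":
    main()
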