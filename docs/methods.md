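# Methods

## Problem setting

Serum small-RNA sequencing after neoadjuvant chemoradiotherapy (NACRT)
yields, per patient, a library of short reads dominated by miRNAs and
tRNA-derived fragments. The analysis asks whether a linear score over a
few such features, possibly combined with routine clinical factors,
predicts pathologic complete response (pCR) at esophagectomy. The package
implements the full path from trimmed reads to score evaluation and
score-stratified survival, with a synthetic cohort generator standing in
for the (non-distributable) patient sera.

## Quantification model

**Read QC and collapsing.** Reads outside 15–45 nt or containing ambiguous
bases are dropped and tallied; identical sequences are collapsed with
summed counts. 15 nt is the shortest fragment we are willing to attribute
to a single reference; 45 nt bounds the small-RNA size range.

**isomiR calling.** Each unique sequence is compared to every mature
miRNA reference with its 5′ end anchored (the study names only 3′
variants; a config switch allows ±2 nt of 5′ shift). For a shared-region
length L ≥ 15, substitutions inside the shared region count toward the
2-mismatch budget; reference bases beyond L are a 3′ deletion, read bases
beyond L a 3′ addition. Among admissible (reference, L) pairs the call
minimises mismatches, then maximises L, then takes the lexicographically
smallest reference name — a total order, so calls are deterministic. A
consequence of preferring fewer mismatches over longer overlap is that a
terminal substitution is reported as a deletion+addition pair rather than
a mismatch; at zero sequencing noise the two descriptions coincide with
the generating feature. Templated and non-templated additions are not
distinguished (that would need genomic flanking context).

**Hemolysis exclusion.** Calls whose source miRNA is one of the ten
hemolysis-associated serum miRNAs (let-7a, miR-223, miR-197, miR-574-3p,
miR-150, miR-451, miR-16, miR-92a, miR-486-5p, miR-122) are removed
before any matrix is formed, since their abundance tracks red-cell lysis
rather than tumor biology.

**tRNA fragments.** Sequences without an isomiR call are aligned
ungapped, fully contained, at every offset of every tRNA reference
(mismatch budget 2; ties: fewest mismatches, leftmost start, smallest
name). Mismatched bases are corrected to the reference, so a fragment is
identified by its reference interval. Classification follows cleavage
geometry relative to the anticodon loop (1-based inclusive coordinates
from a side table): start = 1 and end < loop start → 5′-tRF; start = 1 and
end ≥ loop start → 5′-half; start > 1 → i-tRF. The three rules partition
every valid interval (property-tested). Fragments whose start is internal
and whose end reaches the 3′ terminus also fall to i-tRF; the analysis
recognises no separate 3′-tRF class. Fragment values are summed into one
feature per tRNA family (members share their 5′ sequence by
construction), matching how the tsRNA group is treated downstream.

**Normalization.** Each library is scaled so its retained features total
1,000,000. The denominator is the assigned, post-exclusion count total by
default; a flag normalises by all QC-kept reads instead, since the
original wording ("total number of reads") is ambiguous. The assigned
default makes row sums exactly 10⁶, which several invariants rely on.

## Candidate criteria and group statistics

"Detected" means raw count ≥ 1 before normalization (detection is not
meaningfully definable after scaling). Both thresholds are strict:
detection fraction > 0.8 in the pCR group, median normalized value > 100.
The median condition is applied to both groups conjunctively by default
("either group" is available — the criterion sentence supports both
readings). Continuous comparisons use the two-sided Mann–Whitney U test:
exact enumeration when min(n) ≤ 8 without ties, otherwise the tie- and
continuity-corrected normal approximation, with a U statistic exactly at
its null mean reported as p = 1 (the continuity shift would otherwise push
a perfectly balanced comparison below 1). The continuity correction keeps
the approximation within |Δp| ≤ 0.02 of the exact branch at n = 8 vs 8.
Categorical comparisons use Pearson chi-square without continuity
correction; Fisher's exact test is available behind a flag because a
printed p-value for a table with a zero cell cannot disambiguate which
variant the original analysis used.

## Score construction

**Clinical screen.** Each candidate clinical factor (age, sex, tumor
diameter, cT, cN, cM, endoscopic and overall cCR, post-treatment biopsy,
CEA, SCC, %ΔSUVmax) is tested pCR vs non-pCR with the statistics above;
factors with p < 0.1 enter the clinical model.

**OR-ranked nesting.** "Cross-validated five times with a
learning-to-validation ratio of 8:2" is implemented as stratified 5-fold
CV (each fold is the 20 % validation part); a repeated-random-80/20 mode
exists because the wording supports either. Per fold, a univariate
logistic model per candidate feature is fit on the training part with the
feature scaled to per-100-normalized-unit increments — without the
rescaling, per-unit ORs for features on a ~100 scale are ≈ 1.00 and
unrankable. Features are ordered by mean fold OR, strongest association
first (a literal ascending mode is flag-selectable), ties lexicographic.
Models over the top 1..k features (k ≤ 3), plus the screened clinical
terms for the combined model, are compared by mean cross-validated AUC
(ties favour fewer features), and the winner is refit on all data — the
only way a CV procedure yields a single printed equation.

**Logistic fitting.** Newton maximum likelihood (score tolerance 1e-8,
100 iterations) with Wald 95 % intervals. Constant columns are dropped;
an all-constant design degrades to the intercept-only model with
intercept = logit(prevalence). Complete/quasi-separation (non-convergence
or |coef| > 30) is flagged rather than reported as divergent numbers; an
optional Firth (Jeffreys-prior) fit provides finite coefficients and is
used inside CV folds so a separated fold cannot poison a ranking. The
published equations themselves are shipped as versioned JSON fixtures and
never refit.

**Evaluation.** Scores are oriented so higher means more likely pCR. AUC
uses the Mann–Whitney pair-counting equivalence via mid-ranks (ties count
½). Operating cutoffs maximise the Youden index, ties resolved toward the
lower cutoff; the cutoffs printed for the original models (0.074, −0.112,
−0.589) are carried as fixture metadata only, since the original
selection rule is not recoverable without patient data. Within-CV
classification metrics use predicted probability 0.5 as threshold.
Odds ratios from 2×2 tables use the cross-product estimate with Wald
intervals; any zero cell yields an explicit non-estimable result.

**Survival.** Kaplan–Meier product-limit curves, two-sided log-rank with
1 df, and Cox partial likelihood with Efron tie handling (via lifelines).
Monotone likelihood is flagged. Recurrence-free and overall survival are
both measured from surgery.

## Synthetic cohort generator

The generator's defaults are the study conditions: 30 pCR / 69 non-pCR;
marker features at the reported group medians (let-7b isomiR 160.1/139.1,
miR-93 isomiR 326.7/207.4, tsRNA-Gly group 269.5/144.8 normalized units)
with detection rates compatible with the >80 % filter; clinical rates and
medians per group (overall cCR 40 %/21.7 %, biopsy 0 %/15.9 %, CEA
1.7/2.7 ng/mL log-normal, %ΔSUVmax 76.7/69.6 truncated normal on
[0,100]); exponential survival with pCR hazard ratios 0.4 (OS) and 0.36
(RFS), non-pCR median OS 36 months, uniform administrative censoring over
24–120 months. Counts are zero-inflated negative binomial (dispersion 4,
giving coefficient-of-variation ≈ 0.5 consistent with the reported
ranges): the NB mean is found by bisecting the quantile function so the
*mixture* median under the configured detection probability hits the
configured median, which is what makes the ±15 % median-convergence check
meaningful. Five equal-group background features (median 199,000,
dispersion 50) make up the bulk of each library so per-million
normalization behaves compositionally as in real data; null and decoy
features exercise each selection criterion. Where the study reports only
medians and ranges, distribution families (NB, log-normal, truncated
normal, exponential) are the standard choices for counts, positive
biomarkers, bounded percentages and event times respectively.

Read emission realises a count table as FASTQ: isomiR features produce
the reference with the named 3′ edit applied, tsRNA group features split
their count as evenly as possible across canonical family fragments (one
5′-tRF, one 5′-half, one i-tRF), with per-base substitution noise at a
configurable rate and constant quality strings. Toy references are random
sequences kept mutually dissimilar (every 15-nt window ≥ 3–5
substitutions from unrelated references) so 2-mismatch calling cannot
cross-assign; with zero noise the quantifier inverts the emitter exactly,
which the round-trip tests assert.

A separate deterministic clinical fixture (plug-in quantile sampling of
the group distributions at 3× cohort size, category counts by rounded
proportions, null factors given identical distributions) carries the
clinical effect pattern without Monte-Carlo noise, so the p < 0.1 screen
returns exactly the four clinical-score factors independent of any seed.

**What passing tests do not show.** The generator draws features
independently within sample (no miRNA co-regulation), uses a single
dispersion per feature, ties survival to the true pCR label only, and
emulates neither adapter artefacts, UMIs, nor hemolysis gradients. Results
on it validate the *procedures* — calling, selection, CV ranking,
calibration — not the clinical effect sizes, which only a real cohort can.

## Problem sizes and numerical choices

Simulation-based checks use: 1,000 reads for oracle agreement; 100
replicates × n = 2,000 for logistic parameter recovery from the published
combined model (≥95 % of coefficients within 3 SE); 200 replicates ×
n = 1,000 with near-complete follow-up for Cox recovery of a true hazard
ratio of 0.4 (the [0.32, 0.50] band is ~3.4 SE wide at that event count);
2,000 permutations for type-I calibration (2 Monte-Carlo-SE acceptance
band); a 3× cohort (90/207) for the combined-vs-single-source AUC margin,
where the 99-patient scale is too fold-noisy for a stable comparison.
Global seeds fan out to per-stage seeds as `seed·1000 + offset`, all below
2³¹, so any stage reproduces in isolation.

## Known limitations

Ungapped alignment only (indels beyond terminal 3′ edits are not
modelled); no novel-miRNA discovery or other ncRNA classes; no multiple-
testing correction in selection (by design — the original criteria apply
none); the printed cutoffs of the published models cannot be re-derived
and are treated as metadata; Firth penalization is a pragmatic fallback,
not a claim about how the original separated factor (biopsy) was handled.
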