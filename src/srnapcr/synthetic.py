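"""Synthetic cohorts for exercising the pCR-prediction pipeline end to end.

Patient sera are not distributable, so every downstream stage is developed
and tested against generated data with the statistical structure the
analysis assumes:

* toy mature-miRNA and tRNA references (random sequences kept mutually
  dissimilar so mismatch-tolerant calling is unambiguous), including the
  marker miRNAs and the ten hemolysis-associated miRNAs by name;
* per-sample feature counts from a zero-inflated negative-binomial model
  whose per-group medians are set to the study's reported group medians
  (reads-per-million scale), with high-abundance background features so
  per-library normalization behaves like a real library;
* clinical covariates matching the reported group rates and medians, and
  exponential survival times with a group hazard ratio plus administrative
  censoring;
* optional read emission (FASTQ) so the quantification stage can be driven
  from raw reads and inverted exactly at zero noise.

Everything is reproducible byte-for-byte from the configured seed.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats as st
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import ClinicalRecord
from .quantify import (
    HEMOLYSIS_MIRNAS,
    isomir_feature_id,
    parse_isomir_feature_id,
)

GLY_FAMILY = "tRNA-Gly-CCC/GCC"
GLU_FAMILY = "tRNA-Glu-CTC"

#: Matrix feature ids of the three candidate markers.
LET7B_FEATURE = isomir_feature_id("let-7b-5p", "T", "CTC")
MIR93_FEATURE = isomir_feature_id("miR-93-5p", "", "TTTG")
TSRNA_GLY_FEATURE = GLY_FAMILY

#: Matrix feature id for each published-model sRNA predictor name.
MODEL_FEATURE_KEYS = {
    "let7b_isomir": LET7B_FEATURE,
    "mir93_isomir": MIR93_FEATURE,
    "tsrna_gly_group": TSRNA_GLY_FEATURE,
}

_BASES = np.array(list("ACGT"))


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _min_window_mm(seq: str, probe: str, w: int) -> int:
    """Smallest mismatch count of `probe[:w]` against any w-window of `seq`."""
    best = w
    for i in range(len(seq) - w + 1):
        best = min(best, _hamming(seq[i : i + w], probe[:w]))
    return best


@dataclass
class ReferenceSet:
    """Toy mature-miRNA and tRNA references with anticodon-loop annotation.

    ``trna_refs`` maps name -> (sequence, (loop_start, loop_end)) with
    1-based inclusive loop coordinates; ``family_map`` maps every tRNA to
    its family label; ``group_fragments`` lists, per family, the canonical
    fragments (name, start, end) used when emitting reads for a tsRNA group
    feature.
    """

    mirna_refs: dict[str, str]
    trna_refs: dict[str, tuple[str, tuple[int, int]]]
    family_map: dict[str, str]
    group_fragments: dict[str, list[tuple[str, int, int]]]

    def validate(self) -> None:
        for name, (seq, (lo, hi)) in self.trna_refs.items():
            if not (2 <= lo <= hi <= len(seq) - 1):
                raise ValueError(f"anticodon loop of {name} not strictly inside [2, len-1]")
            if name not in self.family_map:
                raise ValueError(f"tRNA {name} has no family label")
        overlap = set(self.mirna_refs) & set(self.trna_refs)
        if overlap:
            raise ValueError(f"duplicate reference names: {sorted(overlap)}")

    def mirna_fasta(self, path) -> None:
        recs = [SeqRecord(Seq(s), id=n, description="") for n, s in self.mirna_refs.items()]
        SeqIO.write(recs, str(path), "fasta")

    def trna_fasta(self, path) -> None:
        recs = [SeqRecord(Seq(s), id=n, description="") for n, (s, _) in self.trna_refs.items()]
        SeqIO.write(recs, str(path), "fasta")

    def loops_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("trna_name\tloop_start\tloop_end\tfamily\n")
            for n, (_s, (lo, hi)) in self.trna_refs.items():
                fh.write(f"{n}\t{lo}\t{hi}\t{self.family_map[n]}\n")


_MIRNA_NAMES = (
    ["let-7b-5p", "miR-93-5p"]
    + sorted(HEMOLYSIS_MIRNAS)
    + ["miR-21-5p", "miR-155-5p", "miR-24-3p", "miR-320a", "miR-126-3p",
       "miR-30d-5p", "miR-423-5p", "miR-148a-3p"]
)

_GLY_NAMES = ["tRNA-Gly-CCC-1-1", "tRNA-Gly-GCC-2-1", "tRNA-Gly-GCC-3-1", "tRNA-Gly-GCC-5-1"]
_GLU_NAMES = ["tRNA-Glu-CTC-1-1", "tRNA-Glu-CTC-2-1"]
_LOOP = (33, 39)
_SHARED_PREFIX_LEN = 36  # family members share their 5' side up to here


def make_reference_set(seed: int) -> ReferenceSet:
    """Deterministically generate the toy reference set for a seed.

    Sequences are random DNA kept mutually dissimilar (every 15-nt window
    of a reference is >= 3-5 substitutions away from windows of unrelated
    references), so that <=2-mismatch calling cannot cross-assign reads.
    let-7b-5p is forced to end in T so its reported 3'-variant
    (deletion T, addition CTC) is constructible.
    """
    rng = np.random.default_rng(seed)

    def rand_seq(n: int) -> str:
        return "".join(rng.choice(_BASES, n))

    mirnas: dict[str, str] = {}
    for name in _MIRNA_NAMES:
        ln = int(rng.integers(20, 24))
        while True:
            s = rand_seq(ln)
            if name == "let-7b-5p":
                s = s[:-1] + "T"
            if all(_hamming(s[:15], t[:15]) >= 5 for t in mirnas.values()):
                mirnas[name] = s
                break

    mirna_prefixes = [s[:15] for s in mirnas.values()]

    def prefix_clear(seq: str, others: Sequence[str], min_mm_mirna=5, min_mm_other=3) -> bool:
        if any(_min_window_mm(seq, p, 15) < min_mm_mirna for p in mirna_prefixes):
            return False
        for o in others:
            for j in range(len(o) - 14):
                if _min_window_mm(seq, o[j : j + 15], 15) < min_mm_other:
                    return False
        return True

    def make_family(names: list[str], other_seqs: list[str]) -> dict[str, str]:
        while True:
            shared = rand_seq(_SHARED_PREFIX_LEN)
            if prefix_clear(shared, other_seqs):
                break
        fam: dict[str, str] = {}
        for name in names:
            tail_len = int(rng.integers(35, 41))
            while True:
                tail = rand_seq(tail_len)
                seq = shared + tail
                if prefix_clear(seq, other_seqs):
                    fam[name] = seq
                    break
        return fam

    gly = make_family(_GLY_NAMES, [])
    glu = make_family(_GLU_NAMES, list(gly.values()))

    trna_refs = {n: (s, _LOOP) for n, s in {**gly, **glu}.items()}
    family_map = {n: GLY_FAMILY for n in _GLY_NAMES} | {n: GLU_FAMILY for n in _GLU_NAMES}
    group_fragments = {
        GLY_FAMILY: [
            (_GLY_NAMES[0], 1, 30),   # 5'-tRF: stops before the loop
            (_GLY_NAMES[0], 1, 36),   # 5'-half: reaches the loop
            (_GLY_NAMES[1], 18, 48),  # i-tRF: internal start
        ],
        GLU_FAMILY: [(_GLU_NAMES[0], 1, 30), (_GLU_NAMES[1], 20, 40)],
    }
    refs = ReferenceSet(
        mirna_refs=mirnas,
        trna_refs=trna_refs,
        family_map=family_map,
        group_fragments=group_fragments,
    )
    refs.validate()
    return refs


@dataclass(frozen=True)
class FeaturePlan:
    """One simulated feature: target medians and detection rates per group."""

    name: str
    median: tuple[float, float]  # (pCR, non-pCR), reads-per-million scale
    detect: tuple[float, float]  # per-group probability of a nonzero count
    dispersion: float | None = None  # override the config-wide dispersion


def default_feature_plans() -> list[FeaturePlan]:
    """The study conditions: the three markers at their reported group
    medians, null/decoy features exercising each selection criterion, and
    high-abundance equal-group background features that make up the bulk of
    each library so per-million normalization is realistic."""
    return [
        FeaturePlan(LET7B_FEATURE, (160.1, 139.1), (0.90, 0.85)),
        FeaturePlan(MIR93_FEATURE, (326.7, 207.4), (0.90, 0.85)),
        FeaturePlan(TSRNA_GLY_FEATURE, (269.5, 144.8), (1.0, 0.95)),
        # nulls / decoys
        FeaturePlan(isomir_feature_id("miR-21-5p"), (150.0, 150.0), (0.90, 0.90)),
        FeaturePlan(isomir_feature_id("miR-155-5p", "", "T"), (85.0, 85.0), (0.90, 0.90)),
        FeaturePlan(isomir_feature_id("miR-24-3p"), (140.0, 140.0), (0.60, 0.60)),
        FeaturePlan(GLU_FAMILY, (120.0, 120.0), (0.90, 0.90)),
        # background bulk
        FeaturePlan(isomir_feature_id("miR-320a"), (199_000.0, 199_000.0), (1.0, 1.0), 50.0),
        FeaturePlan(isomir_feature_id("miR-126-3p"), (199_000.0, 199_000.0), (1.0, 1.0), 50.0),
        FeaturePlan(isomir_feature_id("miR-30d-5p"), (199_000.0, 199_000.0), (1.0, 1.0), 50.0),
        FeaturePlan(isomir_feature_id("miR-423-5p"), (199_000.0, 199_000.0), (1.0, 1.0), 50.0),
        FeaturePlan(isomir_feature_id("miR-148a-3p"), (199_000.0, 199_000.0), (1.0, 1.0), 50.0),
    ]


def read_scale_feature_plans() -> list[FeaturePlan]:
    """Marker + decoy panel without the background bulk; counts then total
    ~1,000 reads per sample, suitable for FASTQ emission in tests/demos."""
    return [p for p in default_feature_plans() if p.median[0] < 1000]


@dataclass
class GroupClinicalParams:
    age: tuple[float, float, float, float] = (64, 8, 35, 80)  # mean, sd, lo, hi
    male_p: float = 0.867
    tumor_diameter: tuple[float, float, float, float] = (52, 16, 20, 100)
    ct34_p: float = 0.867
    cn13_p: float = 0.700
    cm1_p: float = 0.200
    endoscopic_ccr_p: float = 0.500
    overall_ccr_p: float = 0.400
    biopsy_pos_p: float = 0.0
    cea: tuple[float, float] = (1.7, 0.45)  # (median ng/mL, log-sd)
    scc: tuple[float, float] = (1.0, 0.35)
    suvmax: tuple[float, float] = (76.7, 13.0)  # truncated normal on [0,100]


def default_clinical_params() -> dict[str, GroupClinicalParams]:
    return {
        "pCR": GroupClinicalParams(),
        "non-pCR": GroupClinicalParams(
            age=(65, 8, 46, 80),
            male_p=0.812,
            ct34_p=0.855,
            cn13_p=0.797,
            cm1_p=0.130,
            endoscopic_ccr_p=0.362,
            overall_ccr_p=0.217,
            biopsy_pos_p=0.159,
            cea=(2.7, 0.55),
            scc=(1.2, 0.50),
            suvmax=(69.6, 13.0),
        ),
    }


@dataclass
class SurvivalParams:
    """Exponential event times (months) with a pCR hazard ratio and
    uniform administrative censoring."""

    os_baseline_hazard: float = math.log(2) / 36.0  # non-pCR median OS 36 mo
    os_hr_pcr: float = 0.4
    rfs_baseline_hazard: float = math.log(2) / 24.0
    rfs_hr_pcr: float = 0.36
    censor_low: float = 24.0
    censor_high: float = 120.0


@dataclass
class CohortConfig:
    n_pcr: int = 30
    n_nonpcr: int = 69
    features: list[FeaturePlan] = field(default_factory=default_feature_plans)
    dispersion: float = 4.0
    clinical: dict[str, GroupClinicalParams] = field(default_factory=default_clinical_params)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_pcr < 2:
            raise ValueError("n_pcr must be >= 2")
        if self.n_nonpcr < 2:
            raise ValueError("n_nonpcr must be >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for plan in self.features:
            if min(plan.median) < 0:
                raise ValueError(f"features[{plan.name}].median must be >= 0")
            if not all(0 <= d <= 1 for d in plan.detect):
                raise ValueError(f"features[{plan.name}].detect must be in [0, 1]")
            if plan.dispersion is not None and plan.dispersion <= 0:
                raise ValueError(f"features[{plan.name}].dispersion must be > 0")
        for g, p in self.clinical.items():
            for fname in ("male_p", "ct34_p", "cn13_p", "cm1_p", "endoscopic_ccr_p",
                          "overall_ccr_p", "biopsy_pos_p"):
                v = getattr(p, fname)
                if not 0 <= v <= 1:
                    raise ValueError(f"clinical[{g}].{fname} must be in [0, 1]")
        if self.survival.censor_low <= 0 or self.survival.censor_high <= self.survival.censor_low:
            raise ValueError("survival.censor_low/censor_high must satisfy 0 < low < high")


def null_config(**overrides) -> CohortConfig:
    """A configuration with no group differences anywhere (exchangeable
    labels): feature medians/detection averaged across groups, clinical
    parameters shared, survival hazard ratio 1."""
    base = CohortConfig(**overrides)
    feats = [
        dataclasses.replace(
            p,
            median=((p.median[0] + p.median[1]) / 2,) * 2,
            detect=((p.detect[0] + p.detect[1]) / 2,) * 2,
        )
        for p in base.features
    ]
    shared = default_clinical_params()["non-pCR"]
    base.features = feats
    base.clinical = {"pCR": shared, "non-pCR": shared}
    base.survival = dataclasses.replace(base.survival, os_hr_pcr=1.0, rfs_hr_pcr=1.0)
    return base


@dataclass
class SimulatedSample:
    sample_id: str
    true_group: str  # "pCR" | "non-pCR"
    feature_counts: dict[str, int]
    clinical: ClinicalRecord


def _nb_mu_for_median(median: float, dispersion: float, detect: float) -> float:
    """Mean of a negative binomial whose zero-inflated mixture median is the
    target.

    With detection probability d, the mixture median is the NB quantile at
    q = (0.5 - (1-d))/d, so we invert the NB quantile function in its mean
    (monotone, step-valued) by bisection and take the midpoint of the mean
    interval that yields round(median).
    """
    target = int(round(median))
    if target <= 0:
        return max(median, 0.01)
    if detect <= 0.5:
        # mixture median is 0 regardless; keep the NB centred on the target
        return float(median)
    q = (0.5 - (1.0 - detect)) / detect
    r = dispersion

    def ppf(mu: float) -> float:
        return float(st.nbinom.ppf(q, r, r / (r + mu)))

    hi = max(10.0, 10.0 * median)
    while ppf(hi) < target + 1:
        hi *= 2.0

    def smallest_mu_reaching(t: int) -> float:
        a, b = 1e-3, hi
        for _ in range(60):
            m = 0.5 * (a + b)
            if ppf(m) >= t:
                b = m
            else:
                a = m
        return b

    return 0.5 * (smallest_mu_reaching(target) + smallest_mu_reaching(target + 1))


def table2_patterned_records(scale: int = 3) -> list[ClinicalRecord]:
    """Deterministic clinical cohort carrying the study's clinical effect
    pattern, for exercising the p<0.1 factor screen.

    The four factors the clinical score uses (overall cCR, biopsy, post-CEA,
    %dSUVmax) get their reported group distributions; every other factor is
    given an identical distribution in both groups.  Continuous covariates
    are plug-in quantile grids (value_i = F^-1((i+0.5)/n)) and categorical
    counts are rounded group proportions, so the screen's outcome does not
    depend on any random seed.  ``scale`` multiplies the 30/69 group sizes
    so the planted effects sit clearly inside the threshold.
    """
    from scipy.stats import norm

    n_by_group = {"pCR": 30 * scale, "non-pCR": 69 * scale}
    # (cea_median, cea_logsd), (suv_mean, suv_sd), ccr_p, biopsy_p per group
    planted = {
        "pCR": ((1.7, 0.45), (76.7, 13.0), 0.40, 0.0),
        "non-pCR": ((2.7, 0.55), (69.6, 13.0), 0.217, 0.159),
    }
    null_props = {"male": 0.83, "ct34": 0.86, "cn13": 0.77, "cm1": 0.15, "endo": 0.40}
    records: list[ClinicalRecord] = []
    for group, n in n_by_group.items():
        (cea_med, cea_sd), (suv_m, suv_sd), ccr_p, biopsy_p = planted[group]
        q = (np.arange(n) + 0.5) / n
        cea = np.exp(np.log(cea_med) + cea_sd * norm.ppf(q))
        suv = st.truncnorm.ppf(q, (0 - suv_m) / suv_sd, (100 - suv_m) / suv_sd,
                               loc=suv_m, scale=suv_sd)
        age = norm.ppf(q, loc=64.7, scale=8.0).clip(35, 85)
        diam = norm.ppf(q, loc=52.0, scale=16.0).clip(20, 100)
        scc = np.exp(np.log(1.1) + 0.45 * norm.ppf(q))
        counts = {k: int(round(p * n)) for k, p in null_props.items()}
        n_ccr = int(round(ccr_p * n))
        n_biopsy = int(round(biopsy_p * n))
        # interleave category positives across the quantile order so the
        # binary factors are not correlated with the continuous grids
        def member(i: int, k: int) -> bool:
            return k > 0 and (i * k) % n < k

        for i in range(n):
            records.append(
                ClinicalRecord(
                    age=float(age[i]),
                    sex="M" if member(i, counts["male"]) else "F",
                    tumor_diameter=float(diam[i]),
                    cT="3-4" if member(i, counts["ct34"]) else "1-2",
                    cN="1-3" if member(i, counts["cn13"]) else "0",
                    cM="1(LYM)" if member(i, counts["cm1"]) else "0",
                    endoscopic_cCR=member(i, counts["endo"]),
                    overall_cCR=member((i + 1), n_ccr),
                    biopsy_positive=member((i + 2), n_biopsy),
                    post_CEA=float(cea[i]),
                    post_SCC=float(scc[i]),
                    pct_delta_suvmax=float(suv[i]),
                    pcr_label=(group == "pCR"),
                )
            )
    return records


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return st.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(config: CohortConfig) -> list[SimulatedSample]:
    """Draw a full cohort: counts, clinical covariates and survival times."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = ["pCR"] * config.n_pcr + ["non-pCR"] * config.n_nonpcr

    mu_cache: dict[tuple, float] = {}
    samples: list[SimulatedSample] = []
    counters = {"pCR": 0, "non-pCR": 0}
    for group in groups:
        gi = 0 if group == "pCR" else 1
        counters[group] += 1
        sid = f"{'P' if gi == 0 else 'N'}{counters[group]:03d}"

        counts: dict[str, int] = {}
        for plan in config.features:
            r = plan.dispersion if plan.dispersion is not None else config.dispersion
            key = (plan.name, gi, r)
            if key not in mu_cache:
                mu_cache[key] = _nb_mu_for_median(plan.median[gi], r, plan.detect[gi])
            detected = rng.random() < plan.detect[gi]
            if not detected:
                counts[plan.name] = 0
                continue
            mu = mu_cache[key]
            counts[plan.name] = int(rng.negative_binomial(r, r / (r + mu)))

        cp = config.clinical[group]
        sv = config.survival
        hr_os = sv.os_hr_pcr if gi == 0 else 1.0
        hr_rfs = sv.rfs_hr_pcr if gi == 0 else 1.0
        t_death = rng.exponential(1.0 / (sv.os_baseline_hazard * hr_os))
        t_recur = rng.exponential(1.0 / (sv.rfs_baseline_hazard * hr_rfs))
        censor = rng.uniform(sv.censor_low, sv.censor_high)
        t_rfs_raw = min(t_recur, t_death)

        rec = ClinicalRecord(
            age=float(round(_truncnorm(rng, *cp.age))),
            sex="M" if rng.random() < cp.male_p else "F",
            tumor_diameter=float(round(_truncnorm(rng, *cp.tumor_diameter))),
            cT="3-4" if rng.random() < cp.ct34_p else "1-2",
            cN="1-3" if rng.random() < cp.cn13_p else "0",
            cM="1(LYM)" if rng.random() < cp.cm1_p else "0",
            endoscopic_cCR=bool(rng.random() < cp.endoscopic_ccr_p),
            overall_cCR=bool(rng.random() < cp.overall_ccr_p),
            biopsy_positive=bool(rng.random() < cp.biopsy_pos_p),
            post_CEA=float(np.exp(np.log(cp.cea[0]) + cp.cea[1] * rng.standard_normal())),
            post_SCC=float(np.exp(np.log(cp.scc[0]) + cp.scc[1] * rng.standard_normal())),
            pct_delta_suvmax=float(_truncnorm(rng, cp.suvmax[0], cp.suvmax[1], 0, 100)),
            pcr_label=(gi == 0),
            rfs_time=float(min(t_rfs_raw, censor)),
            rfs_event=bool(t_rfs_raw <= censor),
            os_time=float(min(t_death, censor)),
            os_event=bool(t_death <= censor),
        )
        samples.append(SimulatedSample(sid, group, counts, rec))
    return samples


def emit_reads(
    sample: SimulatedSample,
    refs: ReferenceSet,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[SeqRecord]:
    """Emit FASTQ records realizing a sample's feature counts.

    isomiR features produce the reference sequence with the named 3'
    deletion/addition applied; tsRNA group features split their count as
    evenly as possible across the family's canonical fragments.  Each base
    is substituted independently with probability ``error_rate``; quality
    strings are constant.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)

    templates: list[tuple[str, int]] = []  # (sequence, copies)
    for name in sorted(sample.feature_counts):
        count = sample.feature_counts[name]
        if count < 0:
            raise ValueError(f"negative count for feature {name!r}")
        if count == 0:
            continue
        if name in refs.group_fragments:
            frags = refs.group_fragments[name]
            base, extra = divmod(count, len(frags))
            for i, (tname, start, end) in enumerate(frags):
                c = base + (1 if i < extra else 0)
                if c:
                    templates.append((refs.trna_refs[tname][0][start - 1 : end], c))
        else:
            mirna, deletion, addition = parse_isomir_feature_id(name)
            if mirna not in refs.mirna_refs:
                raise ValueError(f"unknown feature {name!r}")
            ref = refs.mirna_refs[mirna]
            if deletion and not ref.endswith(deletion):
                raise ValueError(f"reference {mirna} does not end with deletion {deletion!r}")
            seq = ref[: len(ref) - len(deletion)] + addition
            templates.append((seq, count))

    records: list[SeqRecord] = []
    idx = 0
    for seq, copies in templates:
        arr = np.array(list(seq))
        for _ in range(copies):
            out = arr.copy()
            if error_rate > 0:
                hits = np.nonzero(rng.random(len(out)) < error_rate)[0]
                for h in hits:
                    out[h] = rng.choice(_BASES[_BASES != out[h]])
            rec = SeqRecord(
                Seq("".join(out)), id=f"{sample.sample_id}_r{idx}", description=""
            )
            rec.letter_annotations["phred_quality"] = [40] * len(out)
            records.append(rec)
            idx += 1
    return records


def write_fastq(records: Sequence[SeqRecord], path) -> None:
    SeqIO.write(records, str(path), "fastq")


def simulate_from_score_model(model, n: int, seed: int):
    """Cohort whose outcome is generated by a given linear log-odds model.

    Covariates are drawn marginally at realistic serum/clinical scales
    (binary rates, reads-per-million negative binomials, log-normal CEA)
    and the pCR label is Bernoulli(sigmoid(score)).  Used for parameter
    recovery: refitting such a cohort should reproduce the generating
    coefficients.  Returns (design DataFrame, outcome array).
    """
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    draws = {
        "overall_cCR": lambda: (rng.random(n) < 27 / 99).astype(float),
        "pct_delta_suvmax": lambda: np.clip(rng.normal(72, 13, n), 0, 100),
        "let7b_isomir": lambda: rng.negative_binomial(4, 4 / (4 + 150), n).astype(float),
        "tsrna_gly_group": lambda: rng.negative_binomial(4, 4 / (4 + 180), n).astype(float),
        "mir93_isomir": lambda: rng.negative_binomial(4, 4 / (4 + 240), n).astype(float),
        "post_CEA": lambda: np.exp(np.log(2.3) + 0.55 * rng.standard_normal(n)),
        "biopsy_positive": lambda: (rng.random(n) < 0.11).astype(float),
    }
    import pandas as pd

    cols = {}
    for name in model.coefficients:
        if name not in draws:
            raise ValueError(f"no covariate generator for predictor {name!r}")
        cols[name] = draws[name]()
    X = pd.DataFrame(cols)
    eta = model.intercept + X.to_numpy() @ np.array(list(model.coefficients.values()))
    y = (rng.random(n) < expit(eta)).astype(float)
    return X, y


def simulate_two_group_exponential(
    n_per_group: int,
    hazard_ratio: float,
    seed: int,
    baseline_hazard: float = math.log(2) / 24.0,
    censor: tuple[float, float] = (60.0, 120.0),
):
    """Exponential survival for two equal groups with a known hazard ratio
    and uniform administrative censoring.  Returns (times, events, group)
    with group=1 carrying the hazard ratio."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    group = np.concatenate([np.ones(n_per_group), np.zeros(n_per_group)])
    lam = np.where(group == 1, hazard_ratio, 1.0) * baseline_hazard
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.uniform(*censor, n)
    return np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int), group


def counts_frame(samples: Sequence[SimulatedSample]):
    import pandas as pd

    df = pd.DataFrame({s.sample_id: s.feature_counts for s in samples}).T
    df.index.name = "sample_id"
    return df[sorted(df.columns)]


def clinical_frame(samples: Sequence[SimulatedSample]):
    import pandas as pd

    rows = []
    for s in samples:
        d = dataclasses.asdict(s.clinical)
        d["sample_id"] = s.sample_id
        d["group"] = s.true_group
        rows.append(d)
    df = pd.DataFrame(rows).set_index("sample_id")
    front = ["group"]
    return df[front + [c for c in df.columns if c not in front]]


def records_from_frame(df) -> list[ClinicalRecord]:
    """Rebuild :class:`ClinicalRecord` objects from a ``clinical_frame``
    table (e.g. read back from clinical.csv)."""
    fields = [f.name for f in dataclasses.fields(ClinicalRecord)]
    records = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in fields}
        for k in ("endoscopic_cCR", "overall_cCR", "biopsy_positive", "pcr_label",
                  "rfs_event", "os_event"):
            kwargs[k] = bool(kwargs[k])
        records.append(ClinicalRecord(**kwargs))
    return records


def truth_frame(config: CohortConfig):
    """Planted-effect table: one row per feature with its configured group
    parameters and whether it is differential."""
    import pandas as pd

    rows = [
        {
            "feature_id": p.name,
            "median_pcr": p.median[0],
            "median_nonpcr": p.median[1],
            "detect_pcr": p.detect[0],
            "detect_nonpcr": p.detect[1],
            "differential": p.median[0] != p.median[1] or p.detect[0] != p.detect[1],
        }
        for p in config.features
    ]
    return pd.DataFrame(rows).set_index("feature_id")
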