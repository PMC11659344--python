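"""Small-RNA quantification: read collapsing, isomiR calling, tRNA-fragment
classification and grouping, hemolysis exclusion, per-library normalization.

The pipeline turns trimmed serum small-RNA reads into one row of a
samples x features expression matrix:

1. collapse identical read sequences and QC-drop malformed ones;
2. call each unique sequence against the mature-miRNA references, allowing
   up to two internal substitutions, with the 5' end anchored — residual 3'
   differences are reported as a terminal deletion/addition pair
   (e.g. ``let-7b-5p|3d:T|3a:CTC``);
3. drop calls whose source miRNA is a known hemolysis marker;
4. align the remaining sequences to the tRNA references (ungapped, up to two
   substitutions, mismatches corrected to the reference), classify each hit
   by cleavage geometry relative to the anticodon loop (5'-tRF / 5'-half /
   i-tRF), and pool hits into per-family tsRNA group features;
5. scale the retained features so each library sums to 1,000,000.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Serum miRNAs reported to track hemolysis; excluded from every matrix.
HEMOLYSIS_MIRNAS: frozenset[str] = frozenset(
    [
        "let-7a",
        "miR-223",
        "miR-197",
        "miR-574-3p",
        "miR-150",
        "miR-451",
        "miR-16",
        "miR-92a",
        "miR-486-5p",
        "miR-122",
    ]
)

MIN_READ_LEN = 15
MAX_READ_LEN = 45
#: Minimum 5'-anchored shared-prefix length for an isomiR call; shorter
#: overlaps are too promiscuous to attribute to a single mature miRNA.
MIN_SHARED_PREFIX = 15
NORMALIZATION_TOTAL = 1_000_000

_VALID = frozenset("ACGT")


class FragClass(enum.Enum):
    """tRNA-fragment class by cleavage geometry on the source tRNA."""

    FIVE_TRF = "5'-tRF"
    FIVE_HALF = "5'-half"
    I_TRF = "i-tRF"


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int


@dataclass(frozen=True)
class IsomiRCall:
    mirna_name: str
    three_prime_deletion: str = ""
    three_prime_addition: str = ""
    internal_mismatches: int = 0
    five_prime_offset: int = 0

    @property
    def feature_id(self) -> str:
        return isomir_feature_id(
            self.mirna_name, self.three_prime_deletion, self.three_prime_addition
        )


@dataclass(frozen=True)
class TsRNACall:
    trna_name: str
    start: int  # 1-based inclusive on the reference
    end: int
    frag_class: FragClass
    mismatches: int
    group_id: str
    corrected_sequence: str

    @property
    def member_id(self) -> str:
        return f"{self.trna_name}:{self.start}-{self.end}"


def isomir_feature_id(name: str, deletion: str = "", addition: str = "") -> str:
    """Canonical isomiR feature identifier ``name|3d:<del>|3a:<add>``."""
    return f"{name}|3d:{deletion}|3a:{addition}"


def parse_isomir_feature_id(feature_id: str) -> tuple[str, str, str]:
    """Inverse of :func:`isomir_feature_id`; bare names mean canonical."""
    if "|" not in feature_id:
        return feature_id, "", ""
    name, d, a = feature_id.split("|")
    if not (d.startswith("3d:") and a.startswith("3a:")):
        raise ValueError(f"malformed isomiR feature id: {feature_id!r}")
    return name, d[3:], a[3:]


class FastqParseError(ValueError):
    def __init__(self, index: int, reason: str):
        self.index = index
        super().__init__(f"FASTQ record {index}: {reason}")


def read_fastq(path) -> list[str]:
    """Read sequences from a FASTQ file (plain text)."""
    seqs = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            seqs.append(str(rec.seq).upper())
    except ValueError as exc:  # Biopython signals malformed records this way
        raise FastqParseError(len(seqs), str(exc)) from exc
    return seqs


def collapse_reads(reads: Iterable[str]) -> tuple[list[CollapsedRead], dict]:
    """Collapse identical sequences; QC-drop N-containing or off-length reads.

    Returns the collapsed list (first-seen order) and a QC log with input,
    kept and dropped tallies.
    """
    counts: dict[str, int] = {}
    n_in = dropped_n = dropped_len = 0
    for seq in reads:
        seq = seq.upper()
        n_in += 1
        if not MIN_READ_LEN <= len(seq) <= MAX_READ_LEN:
            dropped_len += 1
            continue
        if not set(seq) <= _VALID:
            dropped_n += 1
            continue
        counts[seq] = counts.get(seq, 0) + 1
    collapsed = [CollapsedRead(s, c) for s, c in counts.items()]
    qc = {
        "input_reads": n_in,
        "kept_reads": n_in - dropped_n - dropped_len,
        "dropped_ambiguous": dropped_n,
        "dropped_length": dropped_len,
    }
    return collapsed, qc


def call_isomir(
    seq: str,
    mirna_refs: Mapping[str, str],
    max_mm: int = 2,
    min_prefix: int = MIN_SHARED_PREFIX,
    max_five_prime_shift: int = 0,
) -> IsomiRCall | None:
    """Call a read as a (possibly variant) mature miRNA, or return ``None``.

    The read's 5' end is anchored at the reference 5' end (an optional
    ``max_five_prime_shift`` relaxes this by up to +/- that many bases).  For
    a shared-region length L, reference bases beyond L are the 3' deletion
    and read bases beyond L the 3' addition; substitutions inside the shared
    region count toward ``max_mm``.  Among shared-region lengths the call
    minimizes mismatches, then maximizes L; among references it minimizes
    mismatches, then maximizes L, then takes the lexicographically smallest
    name.  Shared regions shorter than ``min_prefix`` never qualify.
    """
    best: tuple[int, int, str, IsomiRCall] | None = None  # (mm, -L, name, call)
    for name in sorted(mirna_refs):
        ref = mirna_refs[name]
        for shift in range(-max_five_prime_shift, max_five_prime_shift + 1):
            # shift > 0: read starts downstream of the reference 5' end
            # (5' trimming); shift < 0: read carries extra 5' bases.
            r = ref[shift:] if shift >= 0 else ref
            s = seq if shift >= 0 else seq[-shift:]
            if shift < 0 and len(seq) < -shift:
                continue
            max_l = min(len(s), len(r))
            if max_l < min_prefix:
                continue
            cand: tuple[int, int] | None = None  # (mm, -L)
            for L in range(max_l, min_prefix - 1, -1):
                mm = sum(1 for a, b in zip(s[:L], r[:L]) if a != b)
                if mm > max_mm:
                    continue
                if cand is None or (mm, -L) < cand:
                    cand = (mm, -L)
            if cand is None:
                continue
            mm, neg_l = cand
            L = -neg_l
            call = IsomiRCall(
                mirna_name=name,
                three_prime_deletion=r[L:],
                three_prime_addition=s[L:],
                internal_mismatches=mm,
                five_prime_offset=shift,
            )
            key = (mm, neg_l, name, call)
            if best is None or key[:3] < best[:3]:
                best = key
    return best[3] if best is not None else None


def classify_trna_fragment(
    start: int, end: int, ref_len: int, loop_start: int, loop_end: int
) -> FragClass:
    """Classify a tRNA fragment by its cleavage interval (1-based inclusive).

    A fragment starting at the tRNA 5' end is a 5'-tRF when it stops before
    the anticodon loop and a 5'-half when it reaches the loop; any fragment
    starting internally is an i-tRF.  The three rules partition every valid
    interval.
    """
    if not (1 <= start <= end <= ref_len):
        raise ValueError(
            f"interval ({start},{end}) outside reference of length {ref_len}"
        )
    if not (2 <= loop_start <= loop_end <= ref_len - 1):
        raise ValueError("anticodon loop must lie strictly inside the reference")
    if start > 1:
        return FragClass.I_TRF
    return FragClass.FIVE_HALF if end >= loop_start else FragClass.FIVE_TRF


def call_tsrna(
    seq: str,
    trna_refs: Mapping[str, tuple[str, tuple[int, int]]],
    family_map: Mapping[str, str],
    max_mm: int = 2,
) -> TsRNACall | None:
    """Align a read to the tRNA references (ungapped, fully contained).

    All start offsets of every reference are scanned; the best hit has the
    fewest substitutions, ties broken by leftmost start, then smallest
    reference name.  Mismatched bases are corrected to the reference, so the
    fragment is identified by its reference interval.  Returns ``None`` when
    no placement has at most ``max_mm`` substitutions.
    """
    n = len(seq)
    sarr = np.frombuffer(seq.encode(), dtype="S1")
    best: tuple[int, int, str] | None = None  # (mm, start, name)
    for name in sorted(trna_refs):
        ref, _loop = trna_refs[name]
        if len(ref) < n:
            continue
        rarr = np.frombuffer(ref.encode(), dtype="S1")
        for start0 in range(len(ref) - n + 1):
            mm = int(np.count_nonzero(rarr[start0 : start0 + n] != sarr))
            if mm > max_mm:
                continue
            key = (mm, start0 + 1, name)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    mm, start, name = best
    ref, (loop_start, loop_end) = trna_refs[name]
    end = start + n - 1
    return TsRNACall(
        trna_name=name,
        start=start,
        end=end,
        frag_class=classify_trna_fragment(start, end, len(ref), loop_start, loop_end),
        mismatches=mm,
        group_id=family_map[name],
        corrected_sequence=ref[start - 1 : end],
    )


@dataclass
class LibraryQuantification:
    """One library's quantification: raw and normalized feature values + QC."""

    raw: dict[str, int]
    normalized: dict[str, float]
    qc: dict = field(default_factory=dict)


def quantify_library(
    reads: Iterable[str],
    refs,
    hemolysis_list: Iterable[str] = HEMOLYSIS_MIRNAS,
    max_mm: int = 2,
    denominator: str = "assigned",
    max_five_prime_shift: int = 0,
) -> LibraryQuantification:
    """Run the full per-library pipeline on an iterable of read sequences.

    ``refs`` is a :class:`srnapcr.synthetic.ReferenceSet` (or anything with
    ``mirna_refs``, ``trna_refs`` and ``family_map`` mappings).  miRNA calls
    take precedence; only unassigned reads are tried against the tRNA
    references, and tsRNA members are summed into their family group
    feature.  ``denominator`` chooses the normalization total: retained
    assigned reads (default) or all QC-kept collapsed reads.
    """
    if denominator not in ("assigned", "all"):
        raise ValueError(f"denominator must be 'assigned' or 'all', got {denominator!r}")
    hemolysis = frozenset(hemolysis_list)
    collapsed, qc = collapse_reads(reads)

    raw: dict[str, int] = {}
    hemolysis_reads = unassigned_reads = 0
    tsrna_members: dict[str, dict[str, int]] = {}
    for cr in collapsed:
        call = call_isomir(
            cr.sequence,
            refs.mirna_refs,
            max_mm=max_mm,
            max_five_prime_shift=max_five_prime_shift,
        )
        if call is not None:
            if call.mirna_name in hemolysis:
                hemolysis_reads += cr.count
                continue
            raw[call.feature_id] = raw.get(call.feature_id, 0) + cr.count
            continue
        tcall = call_tsrna(cr.sequence, refs.trna_refs, refs.family_map, max_mm=max_mm)
        if tcall is not None:
            raw[tcall.group_id] = raw.get(tcall.group_id, 0) + cr.count
            members = tsrna_members.setdefault(tcall.group_id, {})
            key = f"{tcall.member_id}:{tcall.frag_class.value}"
            members[key] = members.get(key, 0) + cr.count
            continue
        unassigned_reads += cr.count

    qc.update(
        hemolysis_reads=hemolysis_reads,
        unassigned_reads=unassigned_reads,
        assigned_reads=sum(raw.values()),
        tsrna_members={g: dict(sorted(m.items())) for g, m in sorted(tsrna_members.items())},
    )
    total = qc["assigned_reads"] if denominator == "assigned" else qc["kept_reads"]
    if total == 0:
        raise ValueError("no assignable reads in library after QC")
    normalized = {f: c * NORMALIZATION_TOTAL / total for f, c in raw.items()}
    return LibraryQuantification(raw=raw, normalized=normalized, qc=qc)


@dataclass
class ExpressionMatrix:
    """Samples x features matrix of library-normalized values plus raw counts."""

    values: pd.DataFrame  # normalized, reads-per-million-scale
    raw: pd.DataFrame  # integer counts, same shape

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_libraries(cls, libs: Mapping[str, LibraryQuantification]) -> "ExpressionMatrix":
        raw = pd.DataFrame({s: q.raw for s, q in libs.items()}).T.fillna(0).astype(int)
        norm = pd.DataFrame({s: q.normalized for s, q in libs.items()}).T.fillna(0.0)
        cols = sorted(raw.columns)
        return cls(values=norm[cols], raw=raw[cols])

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "ExpressionMatrix":
        """Normalize a samples x features count table to 1e6 per row."""
        counts = counts.astype(float)
        totals = counts.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise ValueError(f"sample {bad!r} has zero total count")
        norm = counts.div(totals, axis=0) * NORMALIZATION_TOTAL
        return cls(values=norm, raw=counts.round().astype(int))

    def to_tsv(self, path) -> None:
        self.values.rename_axis("sample_id").to_csv(path, sep="\t")
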