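"""Quantification contracts: collapsing, isomiR calling, tRF classification
and grouping, hemolysis exclusion, normalization, and agreement with
brute-force alignment oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

from srnapcr.quantify import (
    FragClass,
    HEMOLYSIS_MIRNAS,
    call_isomir,
    call_tsrna,
    classify_trna_fragment,
    collapse_reads,
    quantify_library,
)
from srnapcr.synthetic import SimulatedSample, emit_reads, read_scale_feature_plans

from .oracles import brute_isomir, brute_tsrna


class TestCollapse:
    def test_counts_identical_sequences(self):
        reads = ["ACGT" * 5, "ACGT" * 5, "TTTTCCCCAAAAGGGG"]
        collapsed, qc = collapse_reads(reads)
        assert {(c.sequence, c.count) for c in collapsed} == {
            ("ACGT" * 5, 2),
            ("TTTTCCCCAAAAGGGG", 1),
        }
        assert qc["kept_reads"] == 3

    def test_empty_input(self):
        collapsed, qc = collapse_reads([])
        assert collapsed == [] and qc["input_reads"] == 0

    def test_qc_drops_n_and_length(self):
        reads = ["ACGTN" + "A" * 12, "A" * 10, "A" * 50, "ACGT" * 5]
        collapsed, qc = collapse_reads(reads)
        assert qc["dropped_ambiguous"] == 1
        assert qc["dropped_length"] == 2
        assert sum(c.count for c in collapsed) == qc["kept_reads"] == 1

    def test_count_conservation_on_random_reads(self, rng):
        reads = ["".join(rng.choice(list("ACGTN"), rng.integers(10, 50))) for _ in range(1000)]
        collapsed, qc = collapse_reads(reads)
        assert sum(c.count for c in collapsed) + qc["dropped_ambiguous"] + qc["dropped_length"] == 1000


class TestIsomiRCalling:
    def test_reported_let7b_variant(self, refs):
        """A read missing the terminal T and carrying a CTC tail is called
        as the let-7b-5p 3'-variant with zero mismatches."""
        read = refs.mirna_refs["let-7b-5p"][:-1] + "CTC"
        call = call_isomir(read, refs.mirna_refs)
        assert call.mirna_name == "let-7b-5p"
        assert call.three_prime_deletion == "T"
        assert call.three_prime_addition == "CTC"
        assert call.internal_mismatches == 0
        assert call.feature_id == "let-7b-5p|3d:T|3a:CTC"

    def test_identical_read_is_canonical(self, refs):
        name = "miR-21-5p"
        call = call_isomir(refs.mirna_refs[name], refs.mirna_refs)
        assert (call.mirna_name, call.three_prime_deletion, call.three_prime_addition) == (name, "", "")
        assert call.internal_mismatches == 0

    def test_three_substitutions_is_no_call(self, refs):
        seq = list(refs.mirna_refs["miR-93-5p"])
        for i in (2, 7, 12):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        assert call_isomir("".join(seq), refs.mirna_refs) is None

    def test_short_read_never_called(self, refs):
        assert call_isomir("ACGTACGTACGTAC", refs.mirna_refs) is None

    def test_agrees_with_bruteforce_on_random_reads(self, refs, rng):
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), rng.integers(15, 46)))
            mine = call_isomir(seq, refs.mirna_refs)
            theirs = brute_isomir(seq, refs.mirna_refs)
            if theirs is None:
                assert mine is None
            else:
                assert mine is not None
                assert (
                    mine.mirna_name,
                    mine.three_prime_deletion,
                    mine.three_prime_addition,
                    mine.internal_mismatches,
                ) == theirs

    def test_agrees_with_bruteforce_on_perturbed_references(self, refs, rng):
        """Reads derived from references (variants + noise) — the regime
        where calls actually fire."""
        names = list(refs.mirna_refs)
        for _ in range(300):
            ref = refs.mirna_refs[names[rng.integers(len(names))]]
            ndel = int(rng.integers(0, 4))
            seq = ref[: len(ref) - ndel] + "".join(rng.choice(list("ACGT"), rng.integers(0, 4)))
            seq = list(seq)
            for _k in range(rng.integers(0, 3)):
                i = int(rng.integers(len(seq)))
                seq[i] = "ACGT"[rng.integers(4)]
            seq = "".join(seq)
            if len(seq) < 15:
                continue
            mine = call_isomir(seq, refs.mirna_refs)
            theirs = brute_isomir(seq, refs.mirna_refs)
            got = None if mine is None else (
                mine.mirna_name, mine.three_prime_deletion, mine.three_prime_addition, mine.internal_mismatches
            )
            assert got == theirs


class TestTRFClassification:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (1, 30, FragClass.FIVE_TRF),
            (1, 32, FragClass.FIVE_TRF),
            (1, 33, FragClass.FIVE_HALF),
            (1, 35, FragClass.FIVE_HALF),
            (15, 45, FragClass.I_TRF),
            (2, 10, FragClass.I_TRF),
            (40, 71, FragClass.I_TRF),
        ],
    )
    def test_cleavage_rule(self, start, end, expected):
        assert classify_trna_fragment(start, end, 71, 33, 39) is expected

    def test_out_of_bounds_interval_raises(self):
        with pytest.raises(ValueError):
            classify_trna_fragment(0, 30, 71, 33, 39)
        with pytest.raises(ValueError):
            classify_trna_fragment(1, 72, 71, 33, 39)

    @given(
        start=st_h.integers(min_value=1, max_value=71),
        end=st_h.integers(min_value=1, max_value=71),
    )
    @settings(max_examples=300, derandomize=True)
    def test_rules_partition_every_valid_interval(self, start, end):
        if start > end:
            with pytest.raises(ValueError):
                classify_trna_fragment(start, end, 71, 33, 39)
            return
        cls = classify_trna_fragment(start, end, 71, 33, 39)
        matches = [
            start == 1 and end < 33,   # 5'-tRF
            start == 1 and end >= 33,  # 5'-half
            start > 1,                 # i-tRF
        ]
        assert sum(matches) == 1
        assert cls is [FragClass.FIVE_TRF, FragClass.FIVE_HALF, FragClass.I_TRF][matches.index(True)]


class TestTsRNACalling:
    def test_exact_prefix_is_five_trf_in_gly_group(self, refs):
        name = "tRNA-Gly-CCC-1-1"
        seq = refs.trna_refs[name][0][:30]
        call = call_tsrna(seq, refs.trna_refs, refs.family_map)
        assert (call.start, call.end) == (1, 30)
        assert call.frag_class is FragClass.FIVE_TRF
        assert call.group_id == "tRNA-Gly-CCC/GCC"
        assert call.mismatches == 0

    def test_substitution_corrected_to_reference(self, refs):
        name = "tRNA-Gly-CCC-1-1"
        ref = refs.trna_refs[name][0]
        seq = list(ref[:30])
        seq[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[10]]
        call = call_tsrna("".join(seq), refs.trna_refs, refs.family_map)
        assert call.mismatches == 1
        assert call.corrected_sequence == ref[:30]
        assert (call.start, call.end, call.group_id) == (1, 30, "tRNA-Gly-CCC/GCC")

    def test_unrelated_sequence_is_no_call(self, refs, rng):
        # a random 30-mer essentially never sits within 2 mismatches
        seq = "".join(rng.choice(list("ACGT"), 30))
        call = call_tsrna(seq, refs.trna_refs, refs.family_map)
        if call is not None:  # guard against the astronomically unlikely
            assert call.mismatches <= 2

    def test_agrees_with_bruteforce_on_fragment_reads(self, refs, rng):
        names = list(refs.trna_refs)
        for _ in range(300):
            ref = refs.trna_refs[names[rng.integers(len(names))]][0]
            start = int(rng.integers(0, len(ref) - 16))
            ln = int(rng.integers(15, min(45, len(ref) - start) + 1))
            seq = list(ref[start : start + ln])
            for _k in range(rng.integers(0, 3)):
                i = int(rng.integers(len(seq)))
                seq[i] = "ACGT"[rng.integers(4)]
            seq = "".join(seq)
            mine = call_tsrna(seq, refs.trna_refs, refs.family_map)
            theirs = brute_tsrna(seq, refs.trna_refs)
            got = None if mine is None else (mine.trna_name, mine.start, mine.mismatches)
            assert got == theirs


class TestQuantifyLibrary:
    def test_round_trip_recovers_planted_counts(self, refs, read_scale_cohort):
        for sample in read_scale_cohort[:2]:
            reads = [str(r.seq) for r in emit_reads(sample, refs, 0.0, seed=11)]
            q = quantify_library(reads, refs)
            assert q.raw == {k: v for k, v in sample.feature_counts.items() if v > 0}

    def test_hemolysis_reads_excluded_and_trf_renormalized(self, refs):
        reads = [refs.mirna_refs["miR-16"]] * 10 + [refs.trna_refs["tRNA-Gly-CCC-1-1"][0][:30]]
        q = quantify_library(reads, refs)
        assert list(q.normalized) == ["tRNA-Gly-CCC/GCC"]
        assert q.normalized["tRNA-Gly-CCC/GCC"] == pytest.approx(1_000_000)
        assert q.qc["hemolysis_reads"] == 10

    def test_no_output_feature_is_hemolysis_listed(self, refs, read_scale_cohort):
        sample = read_scale_cohort[0]
        counts = dict(sample.feature_counts, **{"let-7a|3d:|3a:": 50, "miR-122|3d:|3a:": 30})
        noisy = SimulatedSample(sample.sample_id, sample.true_group, counts, sample.clinical)
        reads = [str(r.seq) for r in emit_reads(noisy, refs, 0.01, seed=2)]
        q = quantify_library(reads, refs)
        assert all(f.split("|")[0] not in HEMOLYSIS_MIRNAS for f in q.normalized)

    def test_row_sums_to_one_million(self, refs, read_scale_cohort):
        for sample in read_scale_cohort:
            reads = [str(r.seq) for r in emit_reads(sample, refs, 0.02, seed=8)]
            q = quantify_library(reads, refs)
            assert sum(q.normalized.values()) == pytest.approx(1_000_000, rel=1e-6)

    def test_empty_library_raises(self, refs):
        with pytest.raises(ValueError, match="no assignable reads"):
            quantify_library(["ACGTACGTACGTACGTACGTACGT"], refs)

    def test_miRNA_takes_precedence_over_tRNA(self, refs):
        """No read is counted both as an isomiR and as a tsRNA feature."""
        reads = [refs.mirna_refs["miR-21-5p"]] * 3 + [refs.trna_refs["tRNA-Glu-CTC-1-1"][0][:20]] * 2
        q = quantify_library(reads, refs)
        assert q.raw == {"miR-21-5p|3d:|3a:": 3, "tRNA-Glu-CTC": 2}
        assert sum(q.raw.values()) == 5
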