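import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from conftest import random_dna
from pamscape.indel_analysis import (
    AlleleCall,
    AlignmentScoring,
    IndelEvent,
    call_indels,
    summarize_alleles,
    t7e1_indel_fraction,
)
from pamscape.sequence_core import SeqRecord
from pamscape.synthetic_data import generate_mutant_alleles

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


def R(seq):
    return SeqRecord("ref", seq)


def A(seq):
    return SeqRecord("allele", seq)


class TestCallIndels:
    def test_identity_no_events(self):
        call = call_indels(R("ACGTACGT"), A("ACGTACGT"))
        assert call.events == [] and call.net_change == 0

    def test_single_deletion(self):
        call = call_indels(R("ACGTACGT"), A("ACGACGT"))
        assert call.events == [IndelEvent("deletion", 3, 1)]
        assert call.net_change == -1

    def test_single_insertion_left_aligned(self):
        # inserting G into ACGT -> ACGGT; leftmost placement is before the
        # existing G (position 2), per left-normalization
        call = call_indels(R("ACGT"), A("ACGGT"))
        assert call.events == [IndelEvent("insertion", 2, 1, "G")]
        assert call.net_change == 1

    def test_deletion_in_homopolymer_left_aligned(self):
        call = call_indels(R("TTAAAACC"), A("TTAAACC"))
        assert call.events == [IndelEvent("deletion", 2, 1)]

    def test_substitution_only_allele(self):
        call = call_indels(R("ACGTACGT"), A("ACGTTCGT"))
        assert call.events == []
        assert call.substitutions == 1

    def test_multi_event(self):
        # 3 bp deletion and a separated 2 bp insertion
        ref = "ACGTACGTACGTTGCATGCATGCA"
        alleles, _ = generate_mutant_alleles(
            R(ref), [[("deletion", 4, 3), ("insertion", 18, "TT")]]
        )
        call = call_indels(R(ref), alleles[0])
        assert sorted(e.kind for e in call.events) == ["deletion", "insertion"]
        assert call.net_change == -1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            call_indels(R(""), A("ACGT"))

    @given(dna)
    def test_self_alignment_has_zero_events(self, seq):
        call = call_indels(R(seq), A(seq))
        assert call.events == [] and call.substitutions == 0

    def test_net_change_equals_length_difference(self, rng):
        for _ in range(30):
            ref = random_dna(rng, rng.randint(20, 120))
            allele = random_dna(rng, rng.randint(20, 120))
            call = call_indels(R(ref), A(allele))
            assert call.net_change == len(allele) - len(ref)

    def test_alignment_score_matches_independent_gotoh(self, rng):
        from Bio import Align

        scoring = AlignmentScoring()
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
        aligner.open_gap_score = scoring.gap_open
        aligner.extend_gap_score = scoring.gap_extend
        for _ in range(20):
            a = random_dna(rng, rng.randint(5, 40))
            b = random_dna(rng, rng.randint(5, 40))
            assert aligner.score(a, b) == pytest.approx(oracles.nw_affine_score(a, b))

    def test_planted_indel_recovery(self, rng):
        # kind, length and net change recovered exactly; events separated
        # by >= 2x the max gap span so the optimal alignment cannot trade
        # a del+ins pair for cheaper fragmented gaps
        for _ in range(25):
            ref = random_dna(rng, 250)
            events = []
            pos = rng.randint(20, 40)
            for _k in range(rng.randint(1, 3)):
                if pos > 200:
                    break
                if rng.random() < 0.5:
                    length = rng.randint(1, 20)
                    events.append(("deletion", pos, length))
                    pos += length + rng.randint(45, 60)
                else:
                    ins = random_dna(rng, rng.randint(1, 20))
                    events.append(("insertion", pos, ins))
                    pos += rng.randint(45, 60)
            events = [e for e in events if (e[0] == "insertion" or e[1] + e[2] <= 250)]
            if not events:
                continue
            alleles, _ = generate_mutant_alleles(R(ref), [events])
            call = call_indels(R(ref), alleles[0])
            got = sorted((e.kind, e.length) for e in call.events)
            want = sorted(
                (k, len(p) if k == "insertion" else p)
                for k, _, p in events
            )
            assert got == want
            assert call.net_change == len(alleles[0].sequence) - len(ref)


class TestSummarizeAlleles:
    def test_grouping_and_multiplicity(self):
        ev = [IndelEvent("deletion", 3, 2)]
        calls = [
            AlleleCall("a1", list(ev), -2),
            AlleleCall("a2", list(ev), -2),
            AlleleCall("a3", list(ev), -2),
        ]
        report = summarize_alleles(calls)
        lines = report.strip().split("\n")
        assert len(lines) == 2  # header + one group
        assert lines[1].endswith("[×3]")

    def test_empty_header_only(self):
        report = summarize_alleles([])
        assert report.strip().split("\n") == ["allele\tevents\tnet_change\trendering"]

    def test_ordering_by_net_change(self):
        calls = [
            AlleleCall("small", [IndelEvent("deletion", 5, 3)], -3),
            AlleleCall("big", [IndelEvent("deletion", 2, 7)], -7),
        ]
        report = summarize_alleles(calls)
        body = report.strip().split("\n")[1:]
        assert body[0].startswith("big")  # -7 sorts before -3

    def test_rendering_dashes_and_lowercase(self):
        ref = R("ACGTACGT")
        calls = [
            AlleleCall("d", [IndelEvent("deletion", 2, 3)], -3),
            AlleleCall("i", [IndelEvent("insertion", 4, 2, "TT")], 2),
        ]
        report = summarize_alleles(calls, reference=ref)
        assert "AC---CGT [×1]" in report
        assert "ACGTttACGT [×1]" in report


class TestT7E1:
    @pytest.mark.parametrize(
        "uncut, cleaved, frac, indel",
        [
            (100.0, [0.0, 0.0], 0.0, 0.0),
            (25.0, [50.0, 25.0], 0.75, 0.5),
            (0.0, [10.0], 1.0, 1.0),
        ],
    )
    def test_closed_form(self, uncut, cleaved, frac, indel):
        est = t7e1_indel_fraction(uncut, cleaved)
        assert est.cleaved_fraction == pytest.approx(frac)
        assert est.indel_fraction == pytest.approx(indel)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            t7e1_indel_fraction(0.0, [0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            t7e1_indel_fraction(-1.0, [5.0])

    def test_monotone_in_cleaved_signal(self):
        last = -1.0
        for c in range(0, 101, 5):
            est = t7e1_indel_fraction(50.0, [float(c)])
            assert est.indel_fraction > last
            last = est.indel_fraction
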