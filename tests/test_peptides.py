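from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    spanning_kmer_count_closed_form,
    spanning_kmers_enumerated,
    sw_affine_score,
)
from spliceneo.assembly import Contig, revcomp
from spliceneo.peptides import (
    IsoformCall,
    junction_kmers,
    local_align,
    locate_breakpoint,
    longest_orf,
    select_best_isoform,
    translate_frame,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def contig(seq: str, sample="S1") -> Contig:
    return Contig(sample_id=sample, sequence=seq, support=1)


class TestLocalAlign:
    def test_identity(self):
        score, spans = local_align("ACDEFG", "ACDEFG")
        assert score == 12.0
        assert spans == ((0, 6), (0, 6))

    def test_double_gap_beats_mismatch(self):
        score, _ = local_align("ACDEFG", "ACXEFG")
        assert score == 8.0  # 5 matches, two gap opens around the X/D

    def test_no_positive_alignment(self):
        score, spans = local_align("AAAA", "CCCC")
        assert score == 0.0
        assert spans is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACD")

    def test_x_scores_as_mismatch(self):
        full, _ = local_align("AXAAAAA", "AWAAAAA")
        assert full == sw_affine_score("AXAAAAA", "AWAAAAA")

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=150, deadline=None)
    def test_matches_dp_oracle(self, seed):
        rng = random.Random(seed)
        a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 12)))
        b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 12)))
        score, _ = local_align(a, b)
        assert score == pytest.approx(sw_affine_score(a, b), abs=1e-9)


class TestTranslateFrame:
    def test_standard_code(self):
        peptide, stop = translate_frame("ATGGCCTGGTAA", 1)
        assert peptide == "MAW"
        assert stop

    def test_frame_offsets(self):
        seq = "TATGGCCTGG"
        assert translate_frame(seq, 2)[0] == "MAW"

    def test_negative_frame(self):
        seq = revcomp("ATGGCCTGG")
        assert translate_frame(seq, -1)[0] == "MAW"

    def test_stop_truncation(self):
        peptide, stop = translate_frame("ATGTAAGCCGCC", 1)
        assert peptide == "M"
        assert stop

    def test_invalid_frame(self):
        with pytest.raises(ValueError):
            translate_frame("ATG", 4)


class TestSelectBestIsoform:
    WT = "MAWAKDLLHHRRS"

    def _cds(self):
        from Bio.Seq import Seq

        # reverse-translate deterministically via a fixed codon table
        codons = {
            "M": "ATG", "A": "GCC", "W": "TGG", "K": "AAA", "D": "GAT",
            "L": "CTG", "H": "CAT", "R": "CGT", "S": "AGC",
        }
        cds = "".join(codons[aa] for aa in self.WT)
        assert str(Seq(cds).translate()) == self.WT
        return cds

    def test_identity_frame_dominates(self):
        cds = self._cds()
        call = select_best_isoform([contig("GG" + cds)], self.WT)
        assert call.frame == 3
        assert call.peptide == self.WT
        assert call.alignment_score == 2 * len(self.WT)

    def test_reverse_complement_selects_negative_frame(self):
        cds = self._cds()
        call = select_best_isoform([contig(revcomp(cds))], self.WT)
        assert call.frame < 0
        assert call.peptide == self.WT

    def test_empty_contigs_excluded(self):
        call = select_best_isoform([], self.WT)
        assert call.excluded
        assert call.exclusion_reason == "assembly_failure"

    def test_empty_wt_rejected(self):
        with pytest.raises(ValueError):
            select_best_isoform([contig("ATG")], "")


def random_coding(rng: random.Random, n_codons: int) -> str:
    safe = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    return "".join(rng.choice(safe) for _ in range(n_codons))


class TestLocateBreakpoint:
    def _call(self, sequence, frame=1, peptide=None, stop=False):
        pep = peptide if peptide is not None else translate_frame(sequence, frame)[0]
        return IsoformCall(
            sample_id="S1", contig=contig(sequence), frame=frame,
            peptide=pep, premature_stop=stop,
        )

    def test_exact_construction(self):
        rng = random.Random(1)
        up = random_coding(rng, 20)  # 60 nt
        down = random_coding(rng, 20)
        call = locate_breakpoint(self._call(up + down), up, down)
        assert not call.excluded
        assert call.breakpoint_nt == 60
        assert call.breakpoint_residues == {20, 21}

    def test_insertion_between_flanks(self):
        rng = random.Random(2)
        up = random_coding(rng, 20)
        down = random_coding(rng, 20)
        insert = random_coding(rng, 4)  # 12-nt novel insertion
        call = locate_breakpoint(self._call(up + insert + down), up, down)
        assert not call.excluded
        assert call.breakpoint_nt == 60
        # last upstream nt and first inserted nt are in codons 20 and 21
        assert call.breakpoint_residues == {20, 21}
        assert call.region_end_nt == 72

    def test_unrelated_contig_unresolved(self):
        rng = random.Random(3)
        up = random_coding(rng, 20)
        down = random_coding(rng, 20)
        noise = "".join(rng.choice("ACGT") for _ in range(120))
        call = locate_breakpoint(self._call(noise), up, down)
        assert call.excluded
        assert call.exclusion_reason == "breakpoint_unresolved"

    def test_flipped_contig(self):
        rng = random.Random(4)
        up = random_coding(rng, 20)
        down = random_coding(rng, 20)
        seq = revcomp(up + down)
        call = locate_breakpoint(self._call(seq, frame=-1), up, down)
        assert not call.excluded
        assert call.breakpoint_nt == 60
        assert call.breakpoint_residues == {20, 21}

    def test_short_flank_rejected(self):
        call = self._call("ACGT" * 30)
        with pytest.raises(ValueError):
            locate_breakpoint(call, "ACGTACGTACGT", "A" * 40)

    def test_mid_codon_breakpoint_single_residue(self):
        rng = random.Random(5)
        up = random_coding(rng, 20) + "GC"  # 62 nt: junction inside codon 21
        down = "A" + random_coding(rng, 20)
        call = locate_breakpoint(self._call(up + down), up, down)
        assert call.breakpoint_residues == {21}


def make_call(peptide: str, residues: set[int]) -> IsoformCall:
    return IsoformCall(
        sample_id="S1",
        contig=contig("A" * (3 * len(peptide))),
        frame=1,
        peptide=peptide,
        breakpoint_residues=frozenset(residues),
        breakpoint_nt=3 * (min(residues) - 1) + 2,
    )


class TestJunctionKmers:
    def test_counts_per_size(self):
        call = make_call("A" * 20, {10, 11})
        # distinct-by-construction peptide needed for dedup-free counting
        peptide = "".join(AA[i % 20] for i in range(20))
        call.peptide = peptide
        ks = junction_kmers(call, sizes=(8, 9, 10, 11))
        by_size = {}
        for pep, start, size in ks.kmers:
            by_size[size] = by_size.get(size, 0) + 1
        assert by_size == {8: 7, 9: 8, 10: 9, 11: 10}
        assert len(ks) == 34

    def test_short_peptide_excluded(self):
        call = make_call("AWDLKHM", {3, 4})  # length 7
        ks = junction_kmers(call, sizes=(8, 9, 10, 11))
        assert len(ks) == 0
        assert call.excluded
        assert call.exclusion_reason == "short_peptide"

    def test_single_15mer(self):
        peptide = "".join(AA[i % 20] for i in range(15))
        call = make_call(peptide, {8})
        ks = junction_kmers(call, sizes=(15,))
        assert [k[0] for k in ks.kmers] == [peptide]

    def test_excluded_call_rejected(self):
        call = make_call("A" * 20, {10})
        call.exclude("premature_stop")
        with pytest.raises(ValueError):
            junction_kmers(call, sizes=(8,))

    def test_deduplicated(self):
        call = make_call("AAAAAAAAAAAAAAAAAAAA", {10, 11})
        ks = junction_kmers(call, sizes=(8,))
        assert len(ks) == 1  # all 8-mers identical

    def test_region_overlap_rule(self):
        peptide = "".join(AA[i % 20] for i in range(20))
        call = make_call(peptide, {10, 11})
        ks = junction_kmers(call, sizes=(8,), region_residues=(10, 11))
        enumerated = [
            peptide[s - 1 : s + 7]
            for s in range(1, 14)
            if s <= 11 and s + 7 >= 10
        ]
        assert [k[0] for k in ks.kmers] == enumerated

    @given(
        length=st.integers(8, 40),
        p=st.integers(1, 39),
        size=st.sampled_from([8, 9, 10, 11, 15]),
    )
    @settings(max_examples=200, deadline=None)
    def test_closed_form_matches_enumeration(self, length, p, size):
        if p + 1 > length:
            return
        rng = random.Random(length * 1000 + p)
        peptide = "".join(rng.choice(AA) for _ in range(length))
        residues = {p, p + 1}
        enumerated = spanning_kmers_enumerated(peptide, residues, size)
        assert len(enumerated) == spanning_kmer_count_closed_form(
            length, p, size
        )
        if size <= length:
            call = make_call(peptide, residues)
            ks = junction_kmers(call, sizes=(size,))
            assert sorted(set(enumerated)) == sorted(k[0] for k in ks.kmers)


def test_longest_orf_roundtrip():
    rng = random.Random(8)
    cds = "ATG" + random_coding(rng, 30) + "TAA"
    filler = "CCCC"
    protein = longest_orf(filler + cds + filler)
    from Bio.Seq import Seq

    assert protein == str(Seq(cds).translate()).rstrip("*")
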