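"""Data model, I/O, translation and pairwise alignment."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microexon.genome_model import (
    AnnotationError,
    CoordinateError,
    ExonAnnotation,
    FrameError,
    GeneModel,
    SequenceRecord,
    derive_introns,
    extract_mature_cds,
    global_align,
    load_locus,
    revcomp,
    save_locus,
    translate,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestSequenceRecord:
    def test_rejects_non_dna(self):
        with pytest.raises(ValueError):
            SequenceRecord("x", "ACGU")

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            SequenceRecord("x", "")

    def test_uppercases(self):
        assert SequenceRecord("x", "acgtn").seq == "ACGTN"

    def test_circular_fetch_wraps_origin(self):
        rec = SequenceRecord("x", "ACGTACGT", circular=True)
        assert rec.fetch(6, 10) == "GTAC"

    def test_linear_fetch_out_of_range(self):
        rec = SequenceRecord("x", "ACGTACGT")
        with pytest.raises(CoordinateError):
            rec.fetch(6, 10)


class TestAnnotationInvariants:
    def test_end_before_start(self):
        with pytest.raises(CoordinateError):
            ExonAnnotation("e", 100, 50, "+", 1)

    def test_orders_must_be_contiguous(self):
        exons = [
            ExonAnnotation("a", 0, 10, "+", 1),
            ExonAnnotation("b", 20, 30, "+", 3),
        ]
        with pytest.raises(AnnotationError):
            GeneModel("g", exons, "x")

    def test_overlapping_exons_rejected(self):
        exons = [
            ExonAnnotation("a", 0, 15, "+", 1),
            ExonAnnotation("b", 10, 30, "+", 2),
        ]
        with pytest.raises(AnnotationError):
            GeneModel("g", exons, "x")


class TestDeriveIntrons:
    def test_simple_cis_intron(self):
        genome = SequenceRecord("x", "A" * 500)
        model = GeneModel(
            "g",
            [ExonAnnotation("a", 100, 200, "+", 1), ExonAnnotation("b", 300, 400, "+", 2)],
            "x",
        )
        introns = derive_introns(model, genome)
        assert len(introns) == 1
        assert (introns[0].start, introns[0].end, introns[0].kind) == (200, 300, "cis")

    def test_strand_switch_is_trans_junction(self):
        genome = SequenceRecord("x", "A" * 500)
        model = GeneModel(
            "g",
            [ExonAnnotation("a", 100, 200, "+", 1), ExonAnnotation("b", 300, 400, "-", 2)],
            "x",
        )
        introns = derive_introns(model, genome)
        assert introns[0].kind == "trans-junction"
        assert introns[0].start is None and introns[0].end is None

    def test_abutting_exons_rejected(self):
        genome = SequenceRecord("x", "A" * 500)
        model = GeneModel(
            "g",
            [ExonAnnotation("a", 100, 200, "+", 1), ExonAnnotation("b", 200, 300, "+", 2)],
            "x",
        )
        with pytest.raises(AnnotationError):
            derive_introns(model, genome)

    def test_default_locus_has_six_cis_and_two_trans(self, default_locus):
        _, model, _ = default_locus
        kinds = [i.kind for i in model.introns]
        assert kinds.count("cis") == 6
        assert kinds.count("trans-junction") == 2


class TestExtractCds:
    def test_plus_exon_verbatim(self):
        genome = SequenceRecord("x", "AACCGGTTAACC")
        model = GeneModel("g", [ExonAnnotation("a", 2, 8, "+", 1)], "x")
        assert extract_mature_cds(genome, model) == "CCGGTT"

    def test_minus_exon_reverse_complement(self):
        genome = SequenceRecord("x", "AACCGGTTAACC")
        model = GeneModel("g", [ExonAnnotation("a", 2, 8, "-", 1)], "x")
        assert extract_mature_cds(genome, model) == "AACCGG"

    def test_order_governs_not_position(self):
        genome = SequenceRecord("x", "AAATTTCCCGGG")
        exons = [
            ExonAnnotation("late", 0, 3, "+", 2),
            ExonAnnotation("early", 6, 9, "+", 1),
        ]
        model = GeneModel("g", exons, "x")
        assert extract_mature_cds(genome, model) == "CCCAAA"

    def test_default_locus_cds_is_clean_frame(self, default_locus, default_cds):
        assert len(default_cds) % 3 == 0
        protein = translate(default_cds)
        assert "*" not in protein[:-1]


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,expected",
        [("CAT", "H"), ("TGA", "W"), ("", ""), ("ATGTAA", "M*")],
    )
    def test_code4_examples(self, cds, expected):
        assert translate(cds, code=4) == expected

    def test_frame_error(self):
        with pytest.raises(FrameError):
            translate("ACGT")

    @given(dna.filter(lambda s: len(s) % 3 == 0))
    @settings(derandomize=True)
    def test_length_is_one_third(self, cds):
        assert len(translate(cds)) == len(cds) // 3


def _enumerate_alignments(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    """Exhaustive recursion over all global alignments; test oracle."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        options = []
        if i < len(a) and j < len(b):
            options.append((match if a[i] == b[j] else mismatch) + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


class TestGlobalAlign:
    def test_identical(self):
        a, b, score, pct = global_align("ACGTACGTAC", "ACGTACGTAC")
        assert (score, pct) == (10, 100.0)

    def test_one_mismatch(self):
        _, _, score, pct = global_align("ACGTACGTAC", "ACGTTCGTAC")
        assert score == 8
        assert pct == pytest.approx(90.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    @given(dna, dna)
    @settings(derandomize=True, max_examples=150)
    def test_score_matches_exhaustive_enumeration(self, a, b):
        _, _, score, _ = global_align(a, b)
        assert score == _enumerate_alignments(a, b)

    def test_score_matches_biopython(self):
        from Bio import Align

        rng = np.random.default_rng(7)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        for _ in range(25):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(20, 120)))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(20, 120)))
            _, _, score, _ = global_align(a, b)
            assert score == aligner.score(a, b)

    def test_alignment_strings_are_consistent(self):
        a, b, score, _ = global_align("ACGTGGTT", "ACGTT")
        assert a.replace("-", "") == "ACGTGGTT"
        assert b.replace("-", "") == "ACGTT"
        rescored = sum(
            -2 if "-" in (x, y) else (1 if x == y else -1) for x, y in zip(a, b)
        )
        assert rescored == score


@given(st.text(alphabet="ACGTN", min_size=0, max_size=60))
@settings(derandomize=True)
def test_revcomp_involution(seq):
    assert revcomp(revcomp(seq)) == seq


class TestLocusIO:
    def test_two_exon_gff_roundtrip(self, tmp_path):
        genome = SequenceRecord("chr", "ACGT" * 250)
        model = GeneModel(
            "g",
            [ExonAnnotation("a", 100, 200, "+", 1), ExonAnnotation("b", 400, 500, "+", 2)],
            "chr",
        )
        save_locus(genome, model, tmp_path / "g.fa", tmp_path / "g.gff3")
        genome2, model2 = load_locus(tmp_path / "g.fa", tmp_path / "g.gff3")
        assert genome2.seq == genome.seq
        assert model2.n_exons == 2
        assert len([i for i in model2.introns if i.kind == "cis"]) == 1

    def test_default_locus_roundtrip(self, tmp_path, default_locus):
        genome, model, _ = default_locus
        save_locus(genome, model, tmp_path / "g.fa", tmp_path / "g.gff3")
        genome2, model2 = load_locus(tmp_path / "g.fa", tmp_path / "g.gff3")
        assert genome2 == genome
        assert [
            (e.exon_id, e.start, e.end, e.strand, e.mrna_order) for e in model2.exons
        ] == [(e.exon_id, e.start, e.end, e.strand, e.mrna_order) for e in model.exons]

    def test_gff_end_before_start(self, tmp_path):
        (tmp_path / "g.fa").write_text(">chr\n" + "ACGT" * 100 + "\n")
        (tmp_path / "g.gff3").write_text(
            "##gff-version 3\n"
            "chr\t.\texon\t50\t20\t.\t+\t.\tgene_id=g;exon_id=a;exon_number=1\n"
        )
        with pytest.raises(CoordinateError):
            load_locus(tmp_path / "g.fa", tmp_path / "g.gff3")

    def test_gff_exon_beyond_genome(self, tmp_path):
        (tmp_path / "g.fa").write_text(">chr\n" + "ACGT" * 10 + "\n")
        (tmp_path / "g.gff3").write_text(
            "chr\t.\texon\t10\t100\t.\t+\t.\tgene_id=g;exon_id=a;exon_number=1\n"
        )
        with pytest.raises(CoordinateError):
            load_locus(tmp_path / "g.fa", tmp_path / "g.gff3")
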