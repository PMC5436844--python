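"""Read classification and intermediate-contig assembly."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from microexon.assembler import (
    AssemblyParams,
    LocusProvenance,
    ReadClass,
    assemble_intermediates,
    classify_alignment,
    classify_read,
    compute_coverage,
)
from microexon.genome_model import ExonAnnotation, GeneModel, SequenceRecord, derive_introns
from microexon.mapper import AlignmentSegment, MapParams, ReferenceIndex, SplitAlignment, map_read
from microexon.synthetic import (
    cds_reference_id,
    simulate_reads,
)
from microexon.genome_model import extract_mature_cds


@pytest.fixture(scope="module")
def toy_locus():
    rng = np.random.default_rng(77)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    genome = SequenceRecord("toy", seq)
    model = GeneModel(
        "g",
        [
            ExonAnnotation("exA", 900, 1000, "+", 1),
            ExonAnnotation("exB", 1400, 1500, "+", 2),
        ],
        "toy",
    )
    model.introns = derive_introns(model, genome)
    prov = LocusProvenance(model, len(genome), cds_id="g_cds")
    return genome, model, prov


def _aln(ref, strand, segments, score=None, read_id="r"):
    segs = tuple(
        AlignmentSegment(rs, re, fs, fe, mm) for rs, re, fs, fe, mm in segments
    )
    if score is None:
        score = sum(len(s) for s in segs)
    return SplitAlignment(read_id, ref, strand, segs, score)


class TestClassifyAlignment:
    def test_contiguous_across_exon_intron_boundary_is_unspliced(self, toy_locus):
        _, _, prov = toy_locus
        aln = _aln("toy", "+", [(0, 76, 960, 1036, 0)])
        assert classify_alignment(aln, prov) == "unspliced"

    def test_cds_junction_read_is_mature(self, toy_locus):
        _, _, prov = toy_locus
        # the exon A/exon B junction is at CDS offset 100
        aln = _aln("g_cds", "+", [(0, 76, 60, 136, 0)])
        assert classify_alignment(aln, prov) == "mature"

    def test_split_exon_plus_intron_is_intermediate(self, toy_locus):
        _, _, prov = toy_locus
        aln = _aln("toy", "+", [(0, 40, 960, 1000, 0), (40, 76, 1200, 1236, 0)])
        assert classify_alignment(aln, prov) == "intermediate"

    def test_split_all_exonic_supports_no_category(self, toy_locus):
        _, _, prov = toy_locus
        aln = _aln("toy", "+", [(0, 40, 960, 1000, 0), (40, 76, 1400, 1436, 0)])
        assert classify_alignment(aln, prov) is None

    def test_overhang_margin(self, toy_locus):
        _, _, prov = toy_locus
        # only 3 intronic bases: within soft-clip reach, not evidence
        aln = _aln("toy", "+", [(0, 76, 927, 1003, 0)])
        assert classify_alignment(aln, prov) is None


class TestClassifyRead:
    def test_single_category_wins(self, toy_locus):
        _, _, prov = toy_locus
        alns = [_aln("toy", "+", [(0, 76, 960, 1036, 0)])]
        assert classify_read("r", alns, prov).label == "unspliced"

    def test_equal_score_in_two_categories_is_ambiguous(self, toy_locus):
        _, _, prov = toy_locus
        alns = [
            _aln("toy", "+", [(0, 76, 960, 1036, 0)]),
            _aln("g_cds", "+", [(0, 76, 60, 136, 0)]),
        ]
        assert classify_read("r", alns, prov).label == "ambiguous"

    def test_categoryless_placements_are_ambiguous(self, toy_locus):
        _, _, prov = toy_locus
        alns = [_aln("toy", "+", [(0, 76, 910, 986, 0)])]  # wholly inside exon A
        assert classify_read("r", alns, prov).label == "ambiguous"

    def test_no_placement_is_unmapped(self, toy_locus):
        _, _, prov = toy_locus
        assert classify_read("r", [], prov).label == "unmapped"

    def test_lower_scoring_category_is_ignored(self, toy_locus):
        _, _, prov = toy_locus
        alns = [
            _aln("toy", "+", [(0, 76, 960, 1036, 2)], score=72),
            _aln("g_cds", "+", [(0, 76, 60, 136, 0)], score=76),
        ]
        assert classify_read("r", alns, prov).label == "mature"


class TestConfusionMatrix:
    def test_error_free_classification_is_diagonal(self, default_locus, default_naive,
                                                   default_transcripts):
        """Every error-free read maps back to its truth class."""
        import dataclasses

        genome, model, truth = default_locus
        truth = dataclasses.replace(truth, reads={})
        pairs = simulate_reads(
            default_transcripts, genome, default_naive, truth,
            coverage=10, error_rate=0.0, seed=3,
        )
        params = MapParams()
        cds = extract_mature_cds(genome, default_naive)
        cds_id = cds_reference_id(default_naive)
        prov = LocusProvenance(default_naive, len(genome), cds_id=cds_id)
        genome_index = ReferenceIndex(genome, k=params.k)
        cds_index = ReferenceIndex(cds, k=params.k, name=cds_id)
        confusion: Counter = Counter()
        for read_id, seq1, seq2 in pairs:
            for seq, mate_truth in zip((seq1, seq2), truth.reads[read_id]):
                alns = map_read(seq, cds_index, params) + map_read(seq, genome_index, params)
                got = classify_read(read_id, alns, prov).label
                confusion[(mate_truth.expected_class, got)] += 1
        off_diagonal = {k: v for k, v in confusion.items() if k[0] != k[1]}
        assert off_diagonal == {}
        # the informative classes are all represented
        seen = {k[0] for k in confusion}
        assert {"mature", "unspliced", "intermediate", "ambiguous"} <= seen


class TestAssembly:
    def test_same_junction_reads_build_one_contig(self, toy_locus):
        genome, _, prov = toy_locus
        def read_at(exon_from, intron_to, rid):
            seq = genome.seq[exon_from:1000] + genome.seq[1200:intron_to]
            n1 = 1000 - exon_from
            return ReadClass(
                rid, "intermediate",
                _aln("toy", "+", [(0, n1, exon_from, 1000, 0),
                                  (n1, len(seq), 1200, intron_to, 0)], read_id=rid),
                seq,
            )
        reads = [read_at(940, 1230, "a"), read_at(970, 1266, "b")]
        contigs = assemble_intermediates(reads, genome, prov)
        assert len(contigs) == 1
        contig = contigs[0]
        assert contig.blocks == [(940, 1000), (1200, 1266)]
        assert contig.junctions == [(1000, 1200)]
        assert contig.seq == genome.seq[940:1000] + genome.seq[1200:1266]

    def test_small_coordinate_overlap_keeps_contigs_apart(self, toy_locus):
        genome, _, prov = toy_locus
        a = ReadClass(
            "a", "intermediate",
            _aln("toy", "+", [(0, 60, 940, 1000, 0), (60, 76, 1200, 1216, 0)], read_id="a"),
            genome.seq[940:1000] + genome.seq[1200:1216],
        )
        b = ReadClass(
            "b", "intermediate",
            _aln("toy", "+", [(0, 10, 990, 1000, 0), (10, 76, 1300, 1366, 0)], read_id="b"),
            genome.seq[990:1000] + genome.seq[1300:1366],
        )
        params = AssemblyParams(min_reads=1)
        contigs = assemble_intermediates([a, b], genome, prov, params)
        assert len(contigs) == 2  # 10 shared columns < min_overlap

    def test_consensus_majority_corrects_errors(self, toy_locus):
        genome, _, prov = toy_locus
        def read_at(exon_from, intron_to, rid, mutate=None):
            seq = genome.seq[exon_from:1000] + genome.seq[1200:intron_to]
            if mutate is not None:
                seq = seq[:mutate] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[mutate]] + seq[mutate + 1 :]
            n1 = 1000 - exon_from
            return ReadClass(
                rid, "intermediate",
                _aln("toy", "+", [(0, n1, exon_from, 1000, 0),
                                  (n1, len(seq), 1200, intron_to, 0)], read_id=rid),
                seq,
            )
        reads = [read_at(940, 1230, "a"), read_at(940, 1230, "b", mutate=5),
                 read_at(940, 1230, "c")]
        contigs = assemble_intermediates(reads, genome, prov)
        assert contigs[0].seq == genome.seq[940:1000] + genome.seq[1200:1230]

    def test_singleton_pileup_dropped_as_noise(self, toy_locus):
        genome, _, prov = toy_locus
        lone = ReadClass(
            "a", "intermediate",
            _aln("toy", "+", [(0, 40, 960, 1000, 0), (40, 76, 1200, 1236, 0)], read_id="a"),
            genome.seq[960:1000] + genome.seq[1200:1236],
        )
        assert assemble_intermediates([lone], genome, prov) == []

    def test_assembly_idempotent(self, toy_locus):
        genome, _, prov = toy_locus
        def read_at(exon_from, intron_to, rid):
            seq = genome.seq[exon_from:1000] + genome.seq[1200:intron_to]
            n1 = 1000 - exon_from
            return ReadClass(
                rid, "intermediate",
                _aln("toy", "+", [(0, n1, exon_from, 1000, 0),
                                  (n1, len(seq), 1200, intron_to, 0)], read_id=rid),
                seq,
            )
        reads = [read_at(940, 1230, "a"), read_at(970, 1266, "b")]
        contigs = assemble_intermediates(reads, genome, prov)
        as_reads = [
            ReadClass(
                c.contig_id, "intermediate",
                _aln(
                    "toy", "+",
                    [
                        (0, c.blocks[0][1] - c.blocks[0][0], *c.blocks[0], 0),
                        (c.blocks[0][1] - c.blocks[0][0], len(c.seq), *c.blocks[1], 0),
                    ],
                    read_id=c.contig_id,
                ),
                c.seq,
            )
            for c in contigs
        ]
        again = assemble_intermediates(as_reads, genome, prov, AssemblyParams(min_reads=1))
        assert [(c.seq, c.blocks, c.junctions) for c in again] == [
            (c.seq, c.blocks, c.junctions) for c in contigs
        ]


class TestCoverage:
    def test_no_alignments_zero(self):
        depth, mean = compute_coverage([], 0, 50)
        assert mean == 0.0 and depth.sum() == 0

    def test_single_read_uniform_depth(self):
        aln = _aln("toy", "+", [(0, 76, 100, 176, 0)])
        depth, mean = compute_coverage([aln], 100, 176)
        assert mean == 1.0 and set(depth.tolist()) == {1}

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            compute_coverage([], 10, 10)

    def test_default_run_cds_depth_near_configured_coverage(self, run_micro_exon_world):
        assert 30 <= run_micro_exon_world.cds_coverage_mean <= 50
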