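"""Synthetic locus generator, transcript worlds and the read simulator."""

from __future__ import annotations

import logging

import pytest

from microexon.genome_model import extract_mature_cds, revcomp, translate
from microexon.synthetic import (
    ConfigError,
    LocusConfig,
    build_transcript_set,
    generate_locus,
    naive_model,
    simulate_reads,
    write_fastq_pair,
)


class TestGenerateLocus:
    def test_default_structure(self, default_locus):
        _, model, truth = default_locus
        lengths = sorted(len(e) for e in model.exons)
        assert model.n_exons == 9
        assert lengths.count(1) == 1
        assert lengths.count(11) == 1
        assert model.cds_length() == 1605
        assert truth.micro_exon_seq == "C"

    def test_determinism(self):
        a = generate_locus(LocusConfig(seed=5))
        b = generate_locus(LocusConfig(seed=5))
        assert a[0].seq == b[0].seq
        assert [(e.start, e.end) for e in a[1].exons] == [
            (e.start, e.end) for e in b[1].exons
        ]

    def test_seeds_differ(self):
        a = generate_locus(LocusConfig(seed=1))
        b = generate_locus(LocusConfig(seed=2))
        assert a[0].seq != b[0].seq

    @pytest.mark.parametrize("seed", range(100))
    def test_cds_and_micro_exon_properties_over_seeds(self, seed):
        genome, model, truth = generate_locus(LocusConfig(seed=seed))
        cds = extract_mature_cds(genome, model)
        protein = translate(cds)
        assert "*" not in protein[:-1]
        assert protein[truth.cds_offset // 3] == "H"
        # planted micro exon strictly inside the original (pre-split) intron
        m0, m1 = truth.micro_exon
        original = (
            min(truth.upstream_intron[0], truth.downstream_intron[0]),
            max(truth.upstream_intron[1], truth.downstream_intron[1]),
        )
        assert original[0] < m0 and m1 < original[1]
        # motif context in pre-mRNA orientation
        context = genome.seq[m0 - 2 : m1 + 2]
        if truth.strand == "-":
            context = revcomp(context)
        assert context == "GG" + truth.micro_exon_seq + "AA"

    def test_infeasible_config_rejected(self):
        with pytest.raises(ConfigError):
            generate_locus(LocusConfig(cds_length=1604))
        with pytest.raises(ConfigError):
            LocusConfig(strand_blocks=((3, "+"), (2, "-"), (2, "+"))).validate()
        with pytest.raises(ConfigError):
            # micro exon at a block edge has no cis neighbour on both sides
            LocusConfig(strand_blocks=((3, "+"), (4, "-"), (2, "+"))).validate()


class TestNaiveModel:
    def test_annexes_one_base_and_drops_micro_exon(self, default_locus, default_naive):
        genome, model, truth = default_locus
        assert default_naive.n_exons == model.n_exons - 1
        naive_cds = extract_mature_cds(genome, default_naive)
        true_cds = extract_mature_cds(genome, model)
        assert len(naive_cds) == len(true_cds)
        diffs = [i for i, (a, b) in enumerate(zip(true_cds, naive_cds)) if a != b]
        assert diffs == [truth.cds_offset]
        assert naive_cds[truth.cds_offset] == truth.editing_site_base


class TestTranscriptWorlds:
    def test_segment_sequences_self_consistent(self, default_locus, default_transcripts):
        genome, _, _ = default_locus
        for t in default_transcripts:
            parts = []
            for g0, g1, strand in t.segments:
                s = genome.fetch(g0, g1)
                parts.append(revcomp(s) if strand == "-" else s)
            assert "".join(parts) == t.seq

    def test_mature_equals_cds(self, default_transcripts, default_cds):
        mature = next(t for t in default_transcripts if t.name == "Y")
        assert mature.seq == default_cds

    def test_intermediate_junction_composition(self, default_locus, default_transcripts):
        genome, model, truth = default_locus
        m0, m1 = truth.micro_exon
        micro = next(e for e in model.exons if (e.start, e.end) == truth.micro_exon)
        upstream = model.exons[micro.mrna_order - 2]
        w = next(t for t in default_transcripts if t.name == "W")
        x = next(t for t in default_transcripts if t.name == "X")
        # W: 3' of the upstream exon, the micro exon, then downstream intron
        exon_tail = genome.fetch(upstream.end - 20, upstream.end)
        intron_head = genome.fetch(m0, truth.downstream_intron[1])[: 20 + len(w.seq)]
        assert exon_tail + genome.fetch(m0, m1) in w.seq
        assert (exon_tail + intron_head[: 1 + 20]) in w.seq
        # X: 3' of the upstream intron, the micro exon, then the next exon
        downstream = model.exons[micro.mrna_order]
        intron_tail = genome.fetch(m0 - 20, m0)
        exon_head = genome.fetch(downstream.start, downstream.start + 20)
        assert intron_tail + genome.fetch(m0, m1) + exon_head in x.seq

    def test_micro_exon_world_has_no_z(self, default_transcripts):
        assert not any(t.name == "Z" for t in default_transcripts)

    def test_editing_world(self, default_locus, default_cds):
        genome, model, truth = default_locus
        transcripts = build_transcript_set(genome, model, truth, world="editing")
        names = {t.name for t in transcripts}
        assert "Z" in names and "W" not in names and "X" not in names
        z = next(t for t in transcripts if t.name == "Z")
        assert z.seq == (
            default_cds[: truth.cds_offset] + "T" + default_cds[truth.cds_offset + 1 :]
        )
        # the conserved histidine is present in the mature mRNA of both worlds
        mature = next(t for t in transcripts if t.name == "Y")
        assert translate(mature.seq)[truth.cds_offset // 3] == "H"
        assert translate(z.seq)[truth.cds_offset // 3] == "Y"  # pre-editing tyrosine

    def test_unknown_world_rejected(self, default_locus):
        genome, model, truth = default_locus
        with pytest.raises(ValueError):
            build_transcript_set(genome, model, truth, world="chimera")


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, default_locus, default_naive,
                                                   default_transcripts):
        genome, model, truth = default_locus
        import dataclasses

        truth = dataclasses.replace(truth, reads={})
        pairs = simulate_reads(
            default_transcripts, genome, default_naive, truth,
            coverage=3, error_rate=0.0, seed=11,
        )
        by_id = {t.transcript_id: t.seq for t in default_transcripts}
        assert pairs
        for read_id, seq1, seq2 in pairs:
            m1, m2 = truth.reads[read_id]
            src = by_id[m1.transcript_id]
            assert seq1 == (src[m1.start:m1.end] if m1.sense else revcomp(src[m1.start:m1.end]))
            assert seq2 == (src[m2.start:m2.end] if m2.sense else revcomp(src[m2.start:m2.end]))

    def test_pair_count_arithmetic(self, default_locus, default_naive, default_transcripts):
        genome, _, truth = default_locus
        import dataclasses

        truth = dataclasses.replace(truth, reads={})
        mature = [t for t in default_transcripts if t.name == "Y"]
        assert len(mature[0]) == 1605
        mature = [dataclasses.replace(mature[0], weight=1.0)]
        pairs = simulate_reads(
            mature, genome, default_naive, truth, coverage=40, error_rate=0.0, seed=0
        )
        assert len(pairs) == round(40 * 1605 / (2 * 76)) == 422

    def test_fixed_seed_gives_identical_fastq(self, tmp_path, default_locus,
                                              default_naive, default_transcripts):
        genome, _, truth = default_locus
        import dataclasses

        outputs = []
        for run in (1, 2):
            t = dataclasses.replace(truth, reads={})
            pairs = simulate_reads(
                default_transcripts, genome, default_naive, t,
                coverage=2, error_rate=0.01, seed=99,
            )
            p1, p2 = tmp_path / f"r1_{run}.fq", tmp_path / f"r2_{run}.fq"
            write_fastq_pair(pairs, p1, p2)
            outputs.append((p1.read_bytes(), p2.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_short_transcript_skipped_with_warning(self, caplog, default_locus,
                                                   default_naive, default_transcripts):
        genome, _, truth = default_locus
        import dataclasses

        truth = dataclasses.replace(truth, reads={})
        y = next(t for t in default_transcripts if t.name == "Y")
        stub = dataclasses.replace(
            y, transcript_id="stub", seq=y.seq[:100], segments=((y.segments[0][0], y.segments[0][0] + 100, y.segments[0][2]),)
        )
        with caplog.at_level(logging.WARNING):
            pairs = simulate_reads(
                [stub], genome, default_naive, truth, coverage=40, error_rate=0.0, seed=0
            )
        assert pairs == []
        assert any("shorter than insert" in rec.message for rec in caplog.records)
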