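"""Read classification into splicing stages and assembly of intermediate contigs.

A mapped read is assigned one of five labels:

``mature``
    contiguous placement on the mature CDS crossing at least one exon-exon
    junction with at least ``min_overhang`` aligned bases on both sides;
``unspliced``
    contiguous placement on the genome covering at least ``min_overhang``
    exonic and ``min_overhang`` intronic bases (i.e. crossing an exon-intron
    boundary with real overhang on both sides);
``intermediate``
    two-segment (spliced-gap) genome placement whose segments jointly cover at
    least ``min_overhang`` exonic *and* ``min_overhang`` intronic bases -- the
    signature of a partially spliced transcript that retains intron sequence;
``ambiguous``
    maximal-score placements fall in more than one category, or in none (e.g.
    a read wholly inside one exon, which the CDS and the genome explain
    equally well);
``unmapped``
    no valid placement.

The overhang margin keeps 1-3-base spillovers (and the single-base micro exon
itself) from triggering a category on their own.

Intermediate reads are assembled by anchoring them on their genomic alignment
coordinates: reads sharing a spliced junction are stacked into a pileup with a
per-column majority consensus (ties resolved toward the reference base), and
the resulting junction contigs are then greedily overlap-merged on consensus
coordinates.  Contigs supported by fewer than ``min_reads`` reads are dropped
as noise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from microexon.genome_model import GeneModel, SequenceRecord, revcomp
from microexon.mapper import SplitAlignment

__all__ = [
    "ClassifyParams",
    "AssemblyParams",
    "LocusProvenance",
    "ReadClass",
    "AssembledTranscript",
    "classify_alignment",
    "classify_read",
    "assemble_intermediates",
    "compute_coverage",
]


@dataclass(frozen=True)
class ClassifyParams:
    min_overhang: int = 8


@dataclass(frozen=True)
class AssemblyParams:
    min_overlap: int = 20
    max_overlap_mismatch: int = 0
    min_reads: int = 2


class LocusProvenance:
    """Per-base exon/intron annotation of the genome, plus CDS junction geometry."""

    INTERGENIC, EXON, INTRON = 0, 1, 2

    def __init__(self, model: GeneModel, genome_length: int, cds_id: str = "cds"):
        self.model = model
        self.genome_length = genome_length
        self.cds_id = cds_id
        self.genome_id = model.genome_id
        kind = np.zeros(genome_length, dtype=np.int8)
        label: dict[int, str] = {}
        intervals: list[tuple[int, int, str, str]] = []
        for exon in model.exons:
            kind[exon.start : exon.end] = self.EXON
            intervals.append((exon.start, exon.end, "exon", exon.exon_id))
        for intron in model.introns:
            if intron.kind != "cis":
                continue
            kind[intron.start : intron.end] = self.INTRON
            intervals.append((intron.start, intron.end, "intron", intron.intron_id))
        self.kind = kind
        self.intervals = sorted(intervals)
        # CDS exon-exon junction offsets (excluding the two CDS ends)
        offsets = []
        pos = 0
        for exon in sorted(model.exons, key=lambda e: e.mrna_order)[:-1]:
            pos += len(exon)
            offsets.append(pos)
        self.cds_junctions = offsets

    def base_counts(self, start: int, end: int) -> tuple[int, int]:
        """(exonic, intronic) base counts in genome interval [start, end)."""
        window = self.kind[max(start, 0) : min(end, self.genome_length)]
        return int((window == self.EXON).sum()), int((window == self.INTRON).sum())

    def label_runs(self, start: int, end: int) -> list[tuple[int, int, str]]:
        """Contiguous provenance runs within [start, end) as (start, end, label)."""
        runs: list[tuple[int, int, str]] = []
        for istart, iend, kind, name in self.intervals:
            lo, hi = max(start, istart), min(end, iend)
            if lo < hi:
                runs.append((lo, hi, f"{kind}:{name}"))
        covered = sorted(runs)
        out: list[tuple[int, int, str]] = []
        pos = start
        for lo, hi, lab in covered:
            if lo > pos:
                out.append((pos, lo, "intergenic"))
            out.append((lo, hi, lab))
            pos = hi
        if pos < end:
            out.append((pos, end, "intergenic"))
        return out


@dataclass
class ReadClass:
    """Classification outcome for one read (mates are classified independently)."""

    read_id: str
    label: str
    alignment: SplitAlignment | None = None
    read_seq: str | None = None


def classify_alignment(
    aln: SplitAlignment, prov: LocusProvenance, params: ClassifyParams = ClassifyParams()
) -> str | None:
    """Category supported by a single placement, or None if it supports none."""
    ov = params.min_overhang
    if aln.reference_id == prov.cds_id:
        if len(aln.segments) != 1:
            return None
        seg = aln.segments[0]
        for junction in prov.cds_junctions:
            if seg.ref_start + ov <= junction <= seg.ref_end - ov:
                return "mature"
        return None
    if aln.reference_id != prov.genome_id:
        raise ValueError(f"alignment reference {aln.reference_id!r} unknown to this locus")
    exonic = intronic = 0
    for seg in aln.segments:
        e, i = prov.base_counts(seg.ref_start, seg.ref_end)
        exonic += e
        intronic += i
    if exonic < ov or intronic < ov:
        return None
    return "unspliced" if len(aln.segments) == 1 else "intermediate"


def classify_read(
    read_id: str,
    alignments: list[SplitAlignment],
    prov: LocusProvenance,
    params: ClassifyParams = ClassifyParams(),
    read_seq: str | None = None,
) -> ReadClass:
    """Label a read from all its maximal-score placements (CDS and genome).

    The label is a pure function of the placements and the gene model: one
    category at the top score wins; several distinct categories, or none, give
    ``ambiguous``; no placement gives ``unmapped``.
    """
    if not alignments:
        return ReadClass(read_id, "unmapped", None, read_seq)
    best = max(a.score for a in alignments)
    top = sorted((a for a in alignments if a.score == best), key=SplitAlignment.sort_key)
    categories: dict[str, SplitAlignment] = {}
    for aln in top:
        cat = classify_alignment(aln, prov, params)
        if cat is not None and cat not in categories:
            categories[cat] = aln
    if len(categories) == 1:
        label, aln = next(iter(categories.items()))
        return ReadClass(read_id, label, aln, read_seq)
    return ReadClass(read_id, "ambiguous", top[0], read_seq)


# ---------------------------------------------------------------------------
# Assembly of intermediate-stage reads
# ---------------------------------------------------------------------------


@dataclass
class _Pileup:
    columns: dict[int, Counter] = field(default_factory=dict)
    junctions: set[tuple[int, int]] = field(default_factory=set)
    read_ids: list[str] = field(default_factory=list)

    def add_bases(self, ref_start: int, bases: str) -> None:
        for offset, base in enumerate(bases):
            self.columns.setdefault(ref_start + offset, Counter())[base] += 1

    def positions(self) -> set[int]:
        return set(self.columns)

    def consensus_at(self, pos: int, ref_base: str) -> str:
        counts = self.columns[pos]
        top = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == top)
        if ref_base in winners:
            return ref_base
        return winners[0]


@dataclass
class AssembledTranscript:
    """A consensus contig with per-base genomic provenance."""

    contig_id: str
    seq: str
    read_ids: list[str]
    blocks: list[tuple[int, int]]
    junctions: list[tuple[int, int]]
    provenance: list[tuple[int, int, str]]
    coverage: np.ndarray

    @property
    def leftmost(self) -> int:
        return self.blocks[0][0]

    @property
    def mean_coverage(self) -> float:
        return float(self.coverage.mean())


def _pileup_from_read(rc: ReadClass) -> _Pileup:
    aln = rc.alignment
    oriented = rc.read_seq if aln.strand == "+" else revcomp(rc.read_seq)
    pile = _Pileup()
    pile.read_ids.append(rc.read_id)
    for seg in aln.segments:
        pile.add_bases(seg.ref_start, oriented[seg.read_start : seg.read_end])
    if len(aln.segments) == 2:
        pile.junctions.add((aln.segments[0].ref_end, aln.segments[1].ref_start))
    return pile


def _consensus_mismatches(a: _Pileup, b: _Pileup, genome: SequenceRecord, shared) -> int:
    mm = 0
    for pos in shared:
        ref = genome.seq[pos]
        if a.consensus_at(pos, ref) != b.consensus_at(pos, ref):
            mm += 1
    return mm


def _merge(a: _Pileup, b: _Pileup) -> _Pileup:
    merged = _Pileup()
    merged.read_ids = a.read_ids + b.read_ids
    merged.junctions = a.junctions | b.junctions
    merged.columns = {pos: Counter(cnt) for pos, cnt in a.columns.items()}
    for pos, cnt in b.columns.items():
        merged.columns.setdefault(pos, Counter()).update(cnt)
    return merged


def assemble_intermediates(
    reads: list[ReadClass],
    genome: SequenceRecord,
    prov: LocusProvenance,
    params: AssemblyParams = AssemblyParams(),
) -> list[AssembledTranscript]:
    """Assemble intermediate-classified reads into junction contigs.

    Reads sharing the same spliced junction stack into one pileup; pileups are
    then greedily merged in descending coordinate-overlap order whenever the
    overlap is at least ``min_overlap`` columns and the consensus sequences
    disagree in at most ``max_overlap_mismatch`` of them.  Output contigs are
    sorted by leftmost genomic coordinate.
    """
    by_junction: dict[tuple[tuple[int, int], ...], _Pileup] = {}
    for rc in reads:
        if rc.label != "intermediate":
            continue
        if rc.read_seq is None or rc.alignment is None:
            raise ValueError(f"intermediate read {rc.read_id!r} lacks sequence or alignment")
        pile = _pileup_from_read(rc)
        key = tuple(sorted(pile.junctions))
        if key in by_junction:
            by_junction[key] = _merge(by_junction[key], pile)
        else:
            by_junction[key] = pile
    pileups = list(by_junction.values())
    pileups = _greedy_overlap_merge(pileups, genome, params)
    pileups = [p for p in pileups if len(p.read_ids) >= params.min_reads]
    contigs = [_finalize(p, genome, prov) for p in pileups]
    contigs.sort(key=lambda c: c.leftmost)
    for i, contig in enumerate(contigs, start=1):
        contig.contig_id = f"contig_{i}"
    return contigs


def _greedy_overlap_merge(
    pileups: list[_Pileup], genome: SequenceRecord, params: AssemblyParams
) -> list[_Pileup]:
    pileups = list(pileups)
    while True:
        best_pair = None
        best_overlap = 0
        for i in range(len(pileups)):
            pos_i = pileups[i].positions()
            for j in range(i + 1, len(pileups)):
                # contigs carrying different splice junctions are different
                # transcripts; merging them would blur the junction evidence
                # (a sequencing error near a junction can shift a single
                # read's split point by a base or two)
                ji, jj = pileups[i].junctions, pileups[j].junctions
                if ji and jj and ji != jj:
                    continue
                shared = pos_i & pileups[j].positions()
                if len(shared) < params.min_overlap or len(shared) <= best_overlap:
                    continue
                if (
                    _consensus_mismatches(pileups[i], pileups[j], genome, shared)
                    <= params.max_overlap_mismatch
                ):
                    best_pair = (i, j)
                    best_overlap = len(shared)
        if best_pair is None:
            return pileups
        i, j = best_pair
        merged = _merge(pileups[i], pileups[j])
        pileups = [p for k, p in enumerate(pileups) if k not in (i, j)] + [merged]


def _finalize(pile: _Pileup, genome: SequenceRecord, prov: LocusProvenance) -> AssembledTranscript:
    positions = sorted(pile.columns)
    blocks: list[tuple[int, int]] = []
    start = prev = positions[0]
    for pos in positions[1:]:
        if pos != prev + 1:
            blocks.append((start, prev + 1))
            start = pos
        prev = pos
    blocks.append((start, prev + 1))
    seq = "".join(pile.consensus_at(p, genome.seq[p]) for p in positions)
    coverage = np.array([sum(pile.columns[p].values()) for p in positions])
    provenance: list[tuple[int, int, str]] = []
    for bstart, bend in blocks:
        provenance.extend(prov.label_runs(bstart, bend))
    return AssembledTranscript(
        contig_id="contig",
        seq=seq,
        read_ids=sorted(pile.read_ids),
        blocks=blocks,
        junctions=sorted(pile.junctions),
        provenance=provenance,
        coverage=coverage,
    )


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def compute_coverage(
    alignments: list[SplitAlignment],
    start: int,
    end: int,
    reference_id: str | None = None,
) -> tuple[np.ndarray, float]:
    """Per-base depth over reference interval [start, end) plus its mean.

    Each aligned segment base counts once; soft-clipped bases do not count.
    """
    if end <= start:
        raise ValueError(f"empty interval [{start}, {end})")
    depth = np.zeros(end - start, dtype=np.int64)
    for aln in alignments:
        if reference_id is not None and aln.reference_id != reference_id:
            continue
        for seg in aln.segments:
            lo, hi = max(seg.ref_start, start), min(seg.ref_end, end)
            if lo < hi:
                depth[lo - start : hi - start] += 1
    return depth, float(depth.mean())
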