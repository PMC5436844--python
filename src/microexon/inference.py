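"""Micro-exon calling, splice-rule validation, re-annotation and the
editing-vs-micro-exon decision.

The call logic mirrors the two-sided evidence that distinguishes a retained
micro exon from an editing site: one intermediate transcript retains the 5'
part of the annotated intron downstream of the upstream exon (a "W-like"
contig: exonic then intronic provenance) and an independent intermediate
transcript retains the 3' part of the same intron upstream of the downstream
exon ("X-like": intronic then exonic).  If splicing removes the intron from
both sides at positions that leave the two retained intron fragments
overlapping, that overlap is exonic in every transcript -- a micro exon.

Validation checks four splice-rule properties of a call: reading-frame
preservation after re-annotation, conservation of the histidine codon
(mitochondrial genetic code 4) at the codon the micro exon completes, the
group-I requirement that the upstream exon end in T, and the GG / micro exon /
AA sequence context in pre-mRNA orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from microexon.assembler import AssembledTranscript
from microexon.genome_model import (
    AnnotationError,
    ExonAnnotation,
    GeneModel,
    Intron,
    SequenceRecord,
    derive_introns,
    exon_sequence,
    extract_mature_cds,
    revcomp,
    translate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MicroExonCall",
    "HypothesisDecision",
    "infer_microexon",
    "validate_call",
    "reannotate",
    "decide_hypothesis",
]


@dataclass(frozen=True)
class MicroExonCall:
    """An inferred micro exon with its flanking introns and validation flags."""

    start: int
    end: int
    seq: str
    strand: str
    intron_id: str  # annotated intron the call lies in
    upstream_intron: tuple[int, int]  # abuts the call on its mRNA-5' side
    downstream_intron: tuple[int, int]
    w_contig_id: str | None = None
    x_contig_id: str | None = None
    frame_preserved: bool | None = None
    conserved_codon: bool | None = None
    upstream_terminal_t: bool | None = None
    motif_match: bool | None = None

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("micro-exon interval must have length >= 1")
        intervals = sorted([self.upstream_intron, self.downstream_intron])
        if intervals[0][1] != self.start or intervals[1][0] != self.end:
            raise ValueError("flanking introns must abut the micro exon on both sides")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def validated(self) -> bool:
        return bool(
            self.frame_preserved
            and self.conserved_codon
            and self.upstream_terminal_t
            and self.motif_match
        )


@dataclass(frozen=True)
class HypothesisDecision:
    """Outcome of the micro-exon vs RNA-editing decision rule."""

    label: str  # micro_exon | editing | inconclusive
    n_edited_cds_reads: int  # spliced reads carrying the genomic (pre-editing) base
    n_junction_reads: int  # intermediate (W/X-like) reads
    n_mature_reads: int
    min_junction: int


def _contig_shape(contig: AssembledTranscript, strand: str) -> str | None:
    """'W' for exonic->intronic provenance in mRNA sense, 'X' for intronic->exonic."""
    runs = [r for r in contig.provenance if r[2] != "intergenic"]
    if len(runs) < 2:
        return None
    ordered = runs if strand == "+" else runs[::-1]
    first_kind = ordered[0][2].split(":")[0]
    last_kind = ordered[-1][2].split(":")[0]
    if first_kind == "exon" and last_kind == "intron":
        return "W"
    if first_kind == "intron" and last_kind == "exon":
        return "X"
    return None


def _retained_intron_interval(contig: AssembledTranscript, intron: Intron) -> tuple[int, int] | None:
    parts = [
        (start, end)
        for start, end, label in contig.provenance
        if label == f"intron:{intron.intron_id}"
    ]
    if not parts:
        return None
    return min(p[0] for p in parts), max(p[1] for p in parts)


def infer_microexon(
    contigs: list[AssembledTranscript],
    model: GeneModel,
    genome: SequenceRecord,
    max_micro_exon_len: int = 30,
) -> tuple[list[MicroExonCall], list[dict]]:
    """Call micro exons from paired W-like / X-like intermediate contigs.

    Within each annotated cis intron, the genomic overlap between the intron
    fragment retained by a W-like contig and the fragment retained by an
    X-like contig is the candidate micro exon; the annotated intron splits
    into two flanking introns at the overlap boundaries.  Overlaps of zero or
    negative length yield no call; overlaps longer than
    ``max_micro_exon_len`` are rejected.  Contigs supported on one side only
    are reported as half-supported candidates, never as calls.

    Returns ``(calls, half_supported)``; the first valid call per intron wins.
    """
    calls: list[MicroExonCall] = []
    half_supported: list[dict] = []
    for intron in model.introns:
        if intron.kind != "cis":
            continue
        w_like: list[AssembledTranscript] = []
        x_like: list[AssembledTranscript] = []
        for contig in contigs:
            retained = _retained_intron_interval(contig, intron)
            if retained is None:
                continue
            shape = _contig_shape(contig, intron.strand)
            if shape == "W":
                w_like.append(contig)
            elif shape == "X":
                x_like.append(contig)
        if w_like and not x_like:
            half_supported.append(
                {"intron": intron.intron_id, "side": "W", "contigs": [c.contig_id for c in w_like]}
            )
            continue
        if x_like and not w_like:
            half_supported.append(
                {"intron": intron.intron_id, "side": "X", "contigs": [c.contig_id for c in x_like]}
            )
            continue
        found = False
        for w in w_like:
            if found:
                break
            for x in x_like:
                call = _call_from_pair(w, x, intron, genome)
                if call is not None and len(call) <= max_micro_exon_len:
                    calls.append(call)
                    found = True
                    break
                if call is not None:
                    logger.warning(
                        "rejected candidate in %s: overlap length %d exceeds %d",
                        intron.intron_id,
                        len(call),
                        max_micro_exon_len,
                    )
    return calls, half_supported


def _call_from_pair(
    w: AssembledTranscript,
    x: AssembledTranscript,
    intron: Intron,
    genome: SequenceRecord,
) -> MicroExonCall | None:
    w_ret = _retained_intron_interval(w, intron)
    x_ret = _retained_intron_interval(x, intron)
    start = max(w_ret[0], x_ret[0])
    end = min(w_ret[1], x_ret[1])
    if end <= start:
        logger.info(
            "retained intron fragments in %s do not overlap (W %s, X %s)",
            intron.intron_id,
            w_ret,
            x_ret,
        )
        return None
    # the retained fragments, minus the overlap, are the two flanking introns
    flank_a = (min(w_ret[0], x_ret[0]), start)
    flank_b = (end, max(w_ret[1], x_ret[1]))
    # extend flanks to the observed splice junctions (contig gap boundaries)
    for contig in (w, x):
        for gap_start, gap_end in contig.junctions:
            if gap_end == start and gap_start < flank_a[0]:
                flank_a = (gap_start, start)
            if gap_start == end and gap_end > flank_b[1]:
                flank_b = (end, gap_end)
    if intron.strand == "+":
        upstream, downstream = flank_a, flank_b
    else:
        upstream, downstream = flank_b, flank_a
    seq = genome.fetch(start, end)
    if intron.strand == "-":
        seq = revcomp(seq)
    return MicroExonCall(
        start=start,
        end=end,
        seq=seq,
        strand=intron.strand,
        intron_id=intron.intron_id,
        upstream_intron=upstream,
        downstream_intron=downstream,
        w_contig_id=w.contig_id,
        x_contig_id=x.contig_id,
    )


def validate_call(
    call: MicroExonCall, genome: SequenceRecord, model: GeneModel
) -> MicroExonCall:
    """Set the four validation flags on a call (failures are recorded, not raised)."""
    try:
        new_model = reannotate(model, call, genome)
    except (AnnotationError, ValueError):
        return replace(
            call,
            frame_preserved=False,
            conserved_codon=False,
            upstream_terminal_t=False,
            motif_match=_motif_match(call, genome),
        )
    frame = new_model.cds_length() % 3 == 0
    conserved = False
    terminal_t = False
    exons = sorted(new_model.exons, key=lambda e: e.mrna_order)
    micro_idx = next(
        i for i, e in enumerate(exons) if (e.start, e.end) == (call.start, call.end)
    )
    upstream_exon = exons[micro_idx - 1] if micro_idx > 0 else None
    if upstream_exon is not None:
        terminal_t = exon_sequence(genome, upstream_exon).endswith("T")
    if frame:
        cds = extract_mature_cds(genome, new_model)
        offset = new_model.cds_offsets()[exons[micro_idx].exon_id]
        protein = translate(cds, code=4)
        conserved = protein[offset // 3] == "H"
    return replace(
        call,
        frame_preserved=frame,
        conserved_codon=conserved,
        upstream_terminal_t=terminal_t,
        motif_match=_motif_match(call, genome),
    )


def _motif_match(
    call: MicroExonCall,
    genome: SequenceRecord,
    five: str = "GG",
    three: str = "AA",
) -> bool:
    """Pre-mRNA context check: ``five`` immediately 5' and ``three`` immediately 3'."""
    if call.strand == "+":
        up = genome.seq[call.start - len(five) : call.start]
        down = genome.seq[call.end : call.end + len(three)]
    else:
        up = revcomp(genome.seq[call.end : call.end + len(five)])
        down = revcomp(genome.seq[call.start - len(three) : call.start])
    return up == five and down == three


def reannotate(
    model: GeneModel, call: MicroExonCall, genome: SequenceRecord | None = None
) -> GeneModel:
    """Insert the called micro exon: one intron becomes two, exon count rises by one.

    The neighbouring exon boundaries are adjusted to abut the call's flanking
    introns, so an upstream exon that had annexed the first intron base (the
    putative editing site) is truncated accordingly.  Applying the same call
    twice raises an annotation error.
    """
    for exon in model.exons:
        if (exon.start, exon.end) == (call.start, call.end):
            raise AnnotationError("call interval is already an annotated exon")
    host = None
    for intron in model.introns:
        if intron.kind == "cis" and intron.start <= call.start and call.end <= intron.end:
            host = intron
            break
    if host is None:
        raise AnnotationError("call does not fall within an annotated cis intron")
    if host.strand != call.strand:
        raise AnnotationError("call strand disagrees with the host intron")
    upstream = model.exon_by_id(host.upstream_exon_id)
    downstream = model.exon_by_id(host.downstream_exon_id)
    up_iv, down_iv = call.upstream_intron, call.downstream_intron
    if call.strand == "+":
        new_upstream = replace(upstream, end=up_iv[0])
        new_downstream = replace(downstream, start=down_iv[1])
    else:
        new_upstream = replace(upstream, start=up_iv[1])
        new_downstream = replace(downstream, end=down_iv[0])
    if len(new_upstream) < 1 or len(new_downstream) < 1:
        raise AnnotationError("flanking introns would consume a neighbouring exon")
    micro = ExonAnnotation(
        exon_id=f"microexon_{call.start}",
        start=call.start,
        end=call.end,
        strand=call.strand,
        mrna_order=upstream.mrna_order + 1,
    )
    exons = []
    for exon in model.exons:
        if exon.exon_id == upstream.exon_id:
            exons.append(new_upstream)
        elif exon.exon_id == downstream.exon_id:
            exons.append(
                replace(new_downstream, mrna_order=new_downstream.mrna_order + 1)
            )
        elif exon.mrna_order > upstream.mrna_order:
            exons.append(replace(exon, mrna_order=exon.mrna_order + 1))
        else:
            exons.append(exon)
    exons.append(micro)
    new_model = GeneModel(
        gene_id=model.gene_id,
        exons=exons,
        genome_id=model.genome_id,
        complete=model.complete,
    )
    new_model.introns = derive_introns(new_model, genome) if genome is not None else []
    return new_model


def decide_hypothesis(
    class_counts: dict[str, int],
    cds_variant_counts: dict[str, int],
    min_junction: int = 3,
) -> HypothesisDecision:
    """Decide micro_exon vs editing from read-class and focal-site variant counts.

    ``cds_variant_counts`` holds ``unaltered`` (spliced reads carrying the
    genomic base at the focal site -- the hypothetical pre-editing transcript)
    and ``altered`` (spliced reads carrying the changed base).  A micro exon
    is called when no pre-editing spliced read exists and at least
    ``min_junction`` intermediate reads support the retained-intron
    junctions; the editing scenario requires the mirror-image evidence.
    """
    n_junction = class_counts.get("intermediate", 0)
    n_mature = class_counts.get("mature", 0)
    n_z = cds_variant_counts.get("unaltered", 0)
    counts = list(class_counts.values()) + list(cds_variant_counts.values())
    if any(c < 0 for c in counts):
        raise ValueError("negative counts")
    if n_z == 0 and n_junction >= min_junction:
        label = "micro_exon"
    elif n_z >= min_junction and n_junction == 0:
        label = "editing"
    else:
        label = "inconclusive"
    return HypothesisDecision(
        label=label,
        n_edited_cds_reads=n_z,
        n_junction_reads=n_junction,
        n_mature_reads=n_mature,
        min_junction=min_junction,
    )
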