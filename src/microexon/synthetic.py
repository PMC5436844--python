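"""Synthetic loci emulating a trans-spliced, micro-exon-bearing mitochondrial gene.

The generator plants a single-base micro exon (default "C") inside what a
naive annotation would call one intron, flanked by a GG dinucleotide
immediately 5' and AA immediately 3' in pre-mRNA orientation, with the
upstream exon ending in T (the group-I splice signature) and the micro exon
supplying the first base of a CAT (histidine, genetic code 4) codon.  The
gene is fragmented over three same-strand blocks (two of them joined by
trans-splicing), one block on the reverse strand, and includes an 11-nt exon.

Two transcript "worlds" can be built over one locus:

``micro_exon``
    unspliced precursors (one per trans-spliced block), the two intermediate
    transcripts W (3' of the upstream exon + micro exon + 5' of the downstream
    intron) and X (3' of the upstream intron + micro exon + 5' of the
    downstream exon), and the mature mRNA Y;
``editing``
    unspliced precursors, a spliced pre-editing transcript Z (the mature
    sequence with the genomic T at the focal site) and the mature Y carrying
    C -- the read population a U-to-C editing mechanism would produce, with no
    intermediate junction forms.

Every simulated read carries ground truth: source transcript, coordinates,
orientation and the splicing-stage class its error-free placements support
(reads whose placement geometry is undecidable are truth-labelled ambiguous).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from microexon.assembler import ClassifyParams, LocusProvenance, classify_read
from microexon.genome_model import (
    ExonAnnotation,
    GeneModel,
    SequenceRecord,
    derive_introns,
    extract_mature_cds,
    revcomp,
)
from microexon.mapper import MapParams, ReferenceIndex, _candidates_for_diagonals

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "LocusConfig",
    "TranscriptRecord",
    "ReadTruth",
    "TruthRecord",
    "generate_locus",
    "naive_model",
    "build_transcript_set",
    "simulate_reads",
    "write_fastq_pair",
    "make_species_panel",
    "make_divergent_cds",
    "cds_reference_id",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS_CODE4 = {"TAA", "TAG"}
_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SAFE_CODONS = [c for c in _ALL_CODONS if c not in _STOPS_CODE4]
_SAFE_T_CODONS = [c for c in _SAFE_CODONS if c.endswith("T")]


class ConfigError(ValueError):
    """The locus configuration is infeasible."""


# minimum length of the exons neighbouring the micro exon (see _draw_exon_lengths)
_MICRO_NEIGHBOR_MIN = 150


@dataclass(frozen=True)
class LocusConfig:
    """Study conditions for one synthetic locus.

    Defaults emulate the fragmented mitochondrial cox1 structure: nine exons
    totalling 1,605 coding nucleotides, an 11-nt exon 4, a 1-nt micro exon 7
    flanked by two cis introns, and three trans-spliced strand blocks.
    """

    n_exons: int = 9
    cds_length: int = 1605
    exon_length_range: tuple[int, int] = (50, 400)
    short_exon_index: int = 4
    short_exon_length: int = 11
    micro_exon_index: int = 7
    micro_exon_base: str = "C"
    editing_site_base: str = "T"  # the base a naive annotation annexes into the upstream exon
    upstream_exon_terminal_base: str = "T"
    motif_flank_5prime: str = "GG"
    motif_flank_3prime: str = "AA"
    intron_length_range: tuple[int, int] = (150, 600)
    # each of the two introns flanking the micro exon; their combined length
    # (plus the micro exon) stays within intron_length_range
    flank_intron_length_range: tuple[int, int] = (150, 300)
    strand_blocks: tuple[tuple[int, str], ...] = ((3, "+"), (2, "-"), (4, "+"))
    genome_padding: int = 300
    spacer_length: int = 250
    exon_lengths: tuple[int, ...] | None = None
    circular: bool = True
    seed: int = 42

    def validate(self) -> None:
        if self.cds_length % 3 != 0:
            raise ConfigError("cds_length must be a multiple of 3")
        if sum(n for n, _ in self.strand_blocks) != self.n_exons:
            raise ConfigError("strand blocks must partition the exons")
        for _, strand in self.strand_blocks:
            if strand not in "+-":
                raise ConfigError(f"bad block strand {strand!r}")
        # the micro exon needs cis neighbours on both sides, i.e. must sit
        # strictly inside one block
        first = 1
        inside = False
        for n, _ in self.strand_blocks:
            if first < self.micro_exon_index < first + n - 1:
                inside = True
            first += n
        if not inside:
            raise ConfigError("micro exon must lie strictly inside a strand block")
        if self.exon_lengths is not None:
            if len(self.exon_lengths) != self.n_exons:
                raise ConfigError("exon_lengths must list one length per exon")
            if sum(self.exon_lengths) != self.cds_length:
                raise ConfigError("exon_lengths must sum to cds_length")
            if sum(self.exon_lengths[: self.micro_exon_index - 1]) % 3 != 0:
                raise ConfigError("micro exon must start a codon")
        if len(self.micro_exon_base) != 1:
            raise ConfigError("micro exon base must be a single nucleotide")


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript population member with its genomic segment composition."""

    name: str  # precursor | W | X | Y | Z
    transcript_id: str
    seq: str
    weight: float
    segments: tuple[tuple[int, int, str], ...]  # genomic (start, end, strand), transcript order

    def __len__(self) -> int:
        return len(self.seq)

    def provenance_path(self, start: int, end: int) -> list[tuple[int, int, str]]:
        """Genomic intervals underlying transcript coordinates [start, end)."""
        path = []
        offset = 0
        for g0, g1, strand in self.segments:
            seg_len = g1 - g0
            lo, hi = max(start, offset), min(end, offset + seg_len)
            if lo < hi:
                if strand == "+":
                    path.append((g0 + (lo - offset), g0 + (hi - offset), strand))
                else:
                    path.append((g1 - (hi - offset), g1 - (lo - offset), strand))
            offset += seg_len
        return path


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one mate."""

    transcript_id: str
    start: int  # transcript coordinates of the mate
    end: int
    sense: bool  # emitted in transcript sense (True) or reverse complement
    expected_class: str


@dataclass
class TruthRecord:
    """Generator ground truth for closed-loop testing."""

    seed: int
    micro_exon: tuple[int, int]
    micro_exon_seq: str
    strand: str
    upstream_intron: tuple[int, int]
    downstream_intron: tuple[int, int]
    cds_offset: int  # CDS position of the micro-exon base
    editing_site_base: str
    reads: dict[str, tuple[ReadTruth, ReadTruth]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "micro_exon": list(self.micro_exon),
            "micro_exon_seq": self.micro_exon_seq,
            "strand": self.strand,
            "upstream_intron": list(self.upstream_intron),
            "downstream_intron": list(self.downstream_intron),
            "cds_offset": self.cds_offset,
            "editing_site_base": self.editing_site_base,
            "reads": {
                rid: [asdict(m1), asdict(m2)] for rid, (m1, m2) in self.reads.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def cds_reference_id(model: GeneModel) -> str:
    return f"{model.gene_id}_cds"


def _random_dna(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _draw_exon_lengths(config: LocusConfig, rng: np.random.Generator) -> list[int]:
    if config.exon_lengths is not None:
        return list(config.exon_lengths)
    lo, hi = config.exon_length_range
    n = config.n_exons
    fixed = {config.short_exon_index - 1: config.short_exon_length,
             config.micro_exon_index - 1: 1}
    free = [i for i in range(n) if i not in fixed]
    target = config.cds_length - sum(fixed.values())
    for _ in range(10_000):
        lengths = [0] * n
        for i, v in fixed.items():
            lengths[i] = v
        draws = rng.integers(lo, hi + 1, size=len(free) - 1)
        last = target - int(draws.sum())
        if not lo <= last <= hi:
            continue
        for i, v in zip(free[:-1], draws):
            lengths[i] = int(v)
        lengths[free[-1]] = last
        # the micro exon must start a codon: shift the remainder between its
        # upstream neighbour and the exon after it
        q = sum(lengths[: config.micro_exon_index - 1])
        delta = q % 3
        if delta:
            lengths[config.micro_exon_index - 2] -= delta
            lengths[config.micro_exon_index] += delta
        if not all(lo <= lengths[i] <= hi for i in free):
            continue
        # exons neighbouring the micro exon must be long enough that the
        # intermediate transcripts comfortably exceed the library insert
        if (
            lengths[config.micro_exon_index - 2] >= _MICRO_NEIGHBOR_MIN
            and lengths[config.micro_exon_index] >= _MICRO_NEIGHBOR_MIN
        ):
            return lengths
    raise ConfigError("could not draw exon lengths satisfying the constraints")


def _build_cds(config: LocusConfig, lengths: list[int], rng: np.random.Generator) -> str:
    n_codons = config.cds_length // 3
    q = sum(lengths[: config.micro_exon_index - 1])
    kq = q // 3
    codons = [
        _SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), size=n_codons)
    ]
    codons[0] = "ATG"
    codons[-1] = "TAA"
    # the codon the micro exon completes, and the upstream exon's terminal T
    codons[kq] = config.micro_exon_base + "AT"
    codons[kq - 1] = _SAFE_T_CODONS[int(rng.integers(0, len(_SAFE_T_CODONS)))]
    cds = "".join(codons)
    assert cds[q - 1] == config.upstream_exon_terminal_base
    return cds


def _build_micro_flanks(config: LocusConfig, rng: np.random.Generator) -> tuple[str, str]:
    """The two introns flanking the micro exon, with a unique motif context."""
    lo, hi = config.flank_intron_length_range
    motif = config.motif_flank_5prime + config.micro_exon_base + config.motif_flank_3prime
    for _ in range(1000):
        a = int(rng.integers(lo, hi + 1))
        c = int(rng.integers(lo, hi + 1))
        up = (
            config.editing_site_base
            + _random_dna(rng, a - 1 - len(config.motif_flank_5prime))
            + config.motif_flank_5prime
        )
        down = config.motif_flank_3prime + _random_dna(rng, c - 1 - len(config.motif_flank_3prime)) + "G"
        region = up + config.micro_exon_base + down
        if region.count(motif) == 1:
            return up, down
    raise ConfigError("could not draw flanking introns with a unique motif context")


def generate_locus(
    config: LocusConfig = LocusConfig(),
) -> tuple[SequenceRecord, GeneModel, TruthRecord]:
    """Generate a genome, its true (micro-exon-aware) gene model and ground truth.

    Deterministic for a fixed config (the seed is part of the config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = _draw_exon_lengths(config, rng)
    cds = _build_cds(config, lengths, rng)
    # exon sequences in mRNA sense
    exon_seqs: list[str] = []
    pos = 0
    for n in lengths:
        exon_seqs.append(cds[pos : pos + n])
        pos += n
    # intron sequences (pre-mRNA sense) keyed by upstream exon index (0-based)
    micro_up, micro_down = _build_micro_flanks(config, rng)
    ilo, ihi = config.intron_length_range
    introns: dict[int, str] = {}
    first = 0
    micro0 = config.micro_exon_index - 1
    for n, _strand in config.strand_blocks:
        for i in range(first, first + n - 1):
            if i == micro0 - 1:
                introns[i] = micro_up
            elif i == micro0:
                introns[i] = micro_down
            else:
                introns[i] = _random_dna(rng, int(rng.integers(ilo, ihi + 1)) - 1) + "G"
        first += n
    # assemble blocks on the genome
    genome_parts: list[str] = [_random_dna(rng, config.genome_padding)]
    coords: dict[int, tuple[int, int, str]] = {}
    offset = config.genome_padding
    first = 0
    for bi, (n, strand) in enumerate(config.strand_blocks):
        elements: list[tuple[str, int | None]] = []  # (sequence, exon index or None)
        for i in range(first, first + n):
            elements.append((exon_seqs[i], i))
            if i in introns and i < first + n - 1:
                elements.append((introns[i], None))
        block_seq = "".join(seq for seq, _ in elements)
        if strand == "+":
            genome_parts.append(block_seq)
            epos = offset
            for seq, idx in elements:
                if idx is not None:
                    coords[idx] = (epos, epos + len(seq), "+")
                epos += len(seq)
        else:
            genome_parts.append(revcomp(block_seq))
            block_end = offset + len(block_seq)
            epos = 0
            for seq, idx in elements:
                if idx is not None:
                    coords[idx] = (block_end - epos - len(seq), block_end - epos, "-")
                epos += len(seq)
        offset += len(block_seq)
        if bi < len(config.strand_blocks) - 1:
            genome_parts.append(_random_dna(rng, config.spacer_length))
            offset += config.spacer_length
        first += n
    genome_parts.append(_random_dna(rng, config.genome_padding))
    genome = SequenceRecord(
        id="synthetic_mt", seq="".join(genome_parts), circular=config.circular
    )
    exons = [
        ExonAnnotation(
            exon_id=f"exon_{i + 1}",
            start=coords[i][0],
            end=coords[i][1],
            strand=coords[i][2],
            mrna_order=i + 1,
        )
        for i in range(config.n_exons)
    ]
    model = GeneModel(gene_id="cox1_like", exons=exons, genome_id=genome.id)
    model.introns = derive_introns(model, genome)
    rebuilt = extract_mature_cds(genome, model)
    if rebuilt != cds:
        raise RuntimeError("internal inconsistency: reconstructed CDS differs from construction")
    micro = model.exon_by_id(f"exon_{config.micro_exon_index}")
    upstream = model.exon_by_id(f"exon_{config.micro_exon_index - 1}")
    downstream = model.exon_by_id(f"exon_{config.micro_exon_index + 1}")
    if micro.strand == "+":
        up_iv = (upstream.end, micro.start)
        down_iv = (micro.end, downstream.start)
    else:
        up_iv = (micro.end, upstream.start)
        down_iv = (downstream.end, micro.start)
    truth = TruthRecord(
        seed=config.seed,
        micro_exon=(micro.start, micro.end),
        micro_exon_seq=config.micro_exon_base,
        strand=micro.strand,
        upstream_intron=up_iv,
        downstream_intron=down_iv,
        cds_offset=sum(lengths[: config.micro_exon_index - 1]),
        editing_site_base=config.editing_site_base,
    )
    return genome, model, truth


def naive_model(model: GeneModel, truth: TruthRecord) -> GeneModel:
    """The pre-discovery annotation: the micro exon is unknown and its single
    base is annexed to the upstream exon as the putative editing site, so the
    gene appears to have one exon fewer and one long intron."""
    exons_sorted = sorted(model.exons, key=lambda e: e.mrna_order)
    micro_order = next(
        e.mrna_order for e in exons_sorted if (e.start, e.end) == truth.micro_exon
    )
    out: list[ExonAnnotation] = []
    for exon in exons_sorted:
        if exon.mrna_order == micro_order:
            continue
        if exon.mrna_order == micro_order - 1:
            if exon.strand == "+":
                exon = replace(exon, end=exon.end + 1)
            else:
                exon = replace(exon, start=exon.start - 1)
        if exon.mrna_order > micro_order:
            exon = replace(exon, mrna_order=exon.mrna_order - 1)
        out.append(exon)
    naive = GeneModel(gene_id=model.gene_id, exons=out, genome_id=model.genome_id)
    naive.introns = derive_introns(naive)
    return naive


_DEFAULT_WEIGHTS = {"precursor": 2.0, "W": 1.0, "X": 1.0, "Y": 4.0, "Z": 1.0}


def build_transcript_set(
    genome: SequenceRecord,
    model: GeneModel,
    truth: TruthRecord,
    world: str = "micro_exon",
    weights: dict[str, float] | None = None,
) -> list[TranscriptRecord]:
    """Transcript populations of one world over a generated locus.

    ``micro_exon``: per-block unspliced precursors, intermediates W and X and
    the mature Y (no Z).  ``editing``: precursors, the spliced pre-editing
    transcript Z (genomic base at the focal site) and the edited mature Y (no
    junction forms).
    """
    if world not in ("micro_exon", "editing"):
        raise ValueError(f"unknown world {world!r}")
    w = dict(_DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    exons = sorted(model.exons, key=lambda e: e.mrna_order)
    out: list[TranscriptRecord] = []

    # unspliced precursors: one per trans-spliced block (polycistronic stand-in)
    blocks: list[list[ExonAnnotation]] = [[exons[0]]]
    for intron, exon in zip(derive_introns(model), exons[1:]):
        if intron.kind == "cis":
            blocks[-1].append(exon)
        else:
            blocks.append([exon])
    for k, block in enumerate(blocks, start=1):
        strand = block[0].strand
        span = (min(e.start for e in block), max(e.end for e in block))
        seq = genome.fetch(*span)
        if strand == "-":
            seq = revcomp(seq)
        out.append(
            TranscriptRecord(
                name="precursor",
                transcript_id=f"precursor_{k}",
                seq=seq,
                weight=w["precursor"],
                segments=((span[0], span[1], strand),),
            )
        )

    def seq_of(segments: tuple[tuple[int, int, str], ...]) -> str:
        parts = []
        for g0, g1, strand in segments:
            s = genome.fetch(g0, g1)
            parts.append(revcomp(s) if strand == "-" else s)
        return "".join(parts)

    y_segments = tuple((e.start, e.end, e.strand) for e in exons)
    mature = TranscriptRecord(
        name="Y", transcript_id="Y", seq=seq_of(y_segments), weight=w["Y"], segments=y_segments
    )

    m0, m1 = truth.micro_exon
    strand = truth.strand
    micro_order = next(e.mrna_order for e in exons if (e.start, e.end) == truth.micro_exon)
    up_exon = exons[micro_order - 2]
    down_exon = exons[micro_order]
    micro_block = next(b for b in blocks if any((e.start, e.end) == truth.micro_exon for e in b))
    block_span = (min(e.start for e in micro_block), max(e.end for e in micro_block))

    if world == "micro_exon":
        # W: the upstream flanking intron is spliced out, everything else in
        # the block (including the downstream flanking intron) still retained;
        # the canonical W form (3' of the upstream exon + micro exon + 5' of
        # the downstream intron) is the junction neighbourhood of this
        # molecule.  X: mirror image -- only the downstream intron is spliced.
        if strand == "+":
            w_segs = (
                (block_span[0], up_exon.end, "+"),
                (m0, block_span[1], "+"),
            )
            x_segs = (
                (block_span[0], m1, "+"),
                (down_exon.start, block_span[1], "+"),
            )
        else:
            w_segs = (
                (up_exon.start, block_span[1], "-"),
                (block_span[0], m1, "-"),
            )
            x_segs = (
                (m0, block_span[1], "-"),
                (block_span[0], down_exon.end, "-"),
            )
        out.append(TranscriptRecord("W", "W", seq_of(w_segs), w["W"], w_segs))
        out.append(TranscriptRecord("X", "X", seq_of(x_segs), w["X"], x_segs))
        out.append(mature)
    else:
        naive = naive_model(model, truth)
        z_segments = tuple(
            (e.start, e.end, e.strand)
            for e in sorted(naive.exons, key=lambda e: e.mrna_order)
        )
        z_seq = seq_of(z_segments)
        expected = (
            mature.seq[: truth.cds_offset]
            + truth.editing_site_base
            + mature.seq[truth.cds_offset + 1 :]
        )
        if z_seq != expected:
            raise RuntimeError("pre-editing transcript is inconsistent with the locus")
        out.append(TranscriptRecord("Z", "Z", z_seq, w["Z"], z_segments))
        out.append(mature)
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _expected_class(
    transcript: TranscriptRecord,
    start: int,
    end: int,
    genome_index: ReferenceIndex,
    cds_index: ReferenceIndex,
    prov: LocusProvenance,
    map_params: MapParams,
    classify_params: ClassifyParams,
) -> str:
    """Splicing-stage class supported by the error-free mate's ideal placements.

    Candidate placements are scored with the mapper's own scoring rules over
    the diagonals implied by the read's true source coordinates (a diagonal is
    usable only if its underlying block is at least k long, the seeding limit
    of a k-mer mapper), plus the CDS diagonal for spliced sources.  The same
    pure classification rules as the pipeline then yield the label.
    """
    tseq = transcript.seq[start:end]
    path = transcript.provenance_path(start, end)
    length = end - start
    diag_fwd: list[int] = []
    diag_rev: list[int] = []
    offset = 0
    for g0, g1, strand in path:
        seg_len = g1 - g0
        if seg_len >= map_params.k:
            if strand == "+":
                diag_fwd.append(g0 - offset)
            else:
                diag_rev.append(g0 - (length - offset - seg_len))
        offset += seg_len
    candidates = []
    if diag_fwd:
        candidates.extend(
            _candidates_for_diagonals("t", tseq, "+", genome_index, diag_fwd, map_params)
        )
    if diag_rev:
        candidates.extend(
            _candidates_for_diagonals(
                "t", revcomp(tseq), "-", genome_index, diag_rev, map_params
            )
        )
    if transcript.name in ("Y", "Z"):
        candidates.extend(
            _candidates_for_diagonals("t", tseq, "+", cds_index, [start], map_params)
        )
    return classify_read("t", candidates, prov, classify_params).label


def simulate_reads(
    transcripts: list[TranscriptRecord],
    genome: SequenceRecord,
    annotation: GeneModel,
    truth: TruthRecord,
    read_len: int = 76,
    insert_mean: int = 300,
    insert_sd: int = 30,
    coverage: int = 40,
    error_rate: float = 0.005,
    seed: int = 0,
    map_params: MapParams = MapParams(),
    classify_params: ClassifyParams = ClassifyParams(),
) -> list[tuple[str, str, str]]:
    """Simulate unstranded paired-end reads with i.i.d. substitution errors.

    Read pairs per transcript number ``round(weight x coverage x length /
    (2 x read_len))``.  Fragments too long for their transcript are redrawn up
    to three times, then skipped with a warning.  Each fragment is emitted in
    a uniformly random orientation.  Ground truth (source coordinates and the
    expected splicing-stage class of each error-free mate, judged against
    ``annotation`` -- normally the naive pre-discovery model) is appended to
    ``truth.reads``.  Returns ``[(read_id, mate1_seq, mate2_seq), ...]``;
    deterministic for a fixed seed.
    """
    if not transcripts:
        raise ValueError("no transcripts to simulate from")
    if insert_mean < read_len:
        raise ValueError("insert_mean must be at least read_len")
    rng = np.random.default_rng(seed)
    cds = extract_mature_cds(genome, annotation)
    genome_index = ReferenceIndex(genome, k=map_params.k)
    cds_index = ReferenceIndex(cds, k=map_params.k, name=cds_reference_id(annotation))
    prov = LocusProvenance(annotation, len(genome), cds_id=cds_reference_id(annotation))
    pairs: list[tuple[str, str, str]] = []

    def add_errors(seq: str) -> str:
        hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
        if len(hits) == 0:
            return seq
        out = list(seq)
        for i in hits:
            alternatives = [b for b in "ACGT" if b != out[i]]
            out[i] = alternatives[int(rng.integers(0, 3))]
        return "".join(out)

    for t in transcripts:
        n_pairs = round(t.weight * coverage * len(t) / (2 * read_len))
        for i in range(n_pairs):
            insert = None
            for _ in range(4):  # first draw + three redraws
                cand = max(read_len, int(round(rng.normal(insert_mean, insert_sd))))
                if cand <= len(t):
                    insert = cand
                    break
            if insert is None:
                logger.warning(
                    "transcript %s (length %d) shorter than insert; fragment skipped",
                    t.transcript_id,
                    len(t),
                )
                continue
            s = int(rng.integers(0, len(t) - insert + 1))
            frag = t.seq[s : s + insert]
            sense_first = bool(rng.random() < 0.5)
            mate_a = (s, s + read_len, True)  # transcript-sense mate
            mate_b = (s + insert - read_len, s + insert, False)
            a_seq = frag[:read_len]
            b_seq = revcomp(frag[-read_len:])
            cls_a = _expected_class(
                t, mate_a[0], mate_a[1], genome_index, cds_index, prov,
                map_params, classify_params,
            )
            cls_b = _expected_class(
                t, mate_b[0], mate_b[1], genome_index, cds_index, prov,
                map_params, classify_params,
            )
            truth_a = ReadTruth(t.transcript_id, mate_a[0], mate_a[1], True, cls_a)
            truth_b = ReadTruth(t.transcript_id, mate_b[0], mate_b[1], False, cls_b)
            read_id = f"{t.transcript_id}_{i}"
            if sense_first:
                pairs.append((read_id, add_errors(a_seq), add_errors(b_seq)))
                truth.reads[read_id] = (truth_a, truth_b)
            else:
                pairs.append((read_id, add_errors(b_seq), add_errors(a_seq)))
                truth.reads[read_id] = (truth_b, truth_a)
    return pairs


def write_fastq_pair(pairs: list[tuple[str, str, str]], path1, path2, quality: int = 30) -> None:
    """Write mates to two FASTQ files with a constant Phred+33 quality string."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for read_id, seq1, seq2 in pairs:
            q1 = chr(quality + 33) * len(seq1)
            q2 = chr(quality + 33) * len(seq2)
            f1.write(f"@{read_id}\n{seq1}\n+\n{q1}\n")
            f2.write(f"@{read_id}\n{seq2}\n+\n{q2}\n")


def make_species_panel(
    base: LocusConfig = LocusConfig(), n: int = 5
) -> list[tuple[SequenceRecord, GeneModel, TruthRecord, str]]:
    """Independent loci sharing the planted motif context but with freshly
    drawn exon and intron backgrounds -- a stand-in panel of related species."""
    panel = []
    for i in range(n):
        config = replace(base, seed=base.seed + 7919 * (i + 1))
        genome, model, truth = generate_locus(config)
        panel.append((genome, model, truth, f"species_{i + 1}"))
    return panel


def make_divergent_cds(
    genome: SequenceRecord,
    model: GeneModel,
    substitutions: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[str, str]:
    """A partner CDS differing only by third-position synonymous substitutions.

    ``substitutions`` maps exon_id to the number of substitutions to plant in
    that exon (default: three in exon 2 and two in exon 9).  Substituted
    codons lie at least one codon away from exon boundaries (never at splicing
    sites).  Returns ``(cds, partner_cds)``.
    """
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[4].forward_table
    if substitutions is None:
        substitutions = {"exon_2": 3, "exon_9": 2}
    rng = np.random.default_rng(seed)
    cds = extract_mature_cds(genome, model)
    offsets = model.cds_offsets()
    partner = list(cds)
    for exon_id, count in substitutions.items():
        exon = model.exon_by_id(exon_id)
        off = offsets[exon_id]
        lo = off + 3
        hi = off + len(exon) - 3
        codon_indices = [k for k in range(-(-lo // 3), hi // 3) if 3 * k + 2 < hi and 3 * k >= lo]
        rng.shuffle(codon_indices)
        planted = 0
        for k in codon_indices:
            if planted == count:
                break
            codon = cds[3 * k : 3 * k + 3]
            if codon in _STOPS_CODE4:
                continue
            aa = table.get(codon)
            options = [
                b
                for b in "ACGT"
                if b != codon[2] and table.get(codon[:2] + b) == aa
            ]
            if not options:
                continue
            partner[3 * k + 2] = options[int(rng.integers(0, len(options)))]
            planted += 1
        if planted < count:
            raise ValueError(f"could not place {count} synonymous substitutions in {exon_id}")
    return cds, "".join(partner)
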