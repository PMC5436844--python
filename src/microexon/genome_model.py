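"""Sequence/annotation data model, FASTA+GFF3 I/O, translation and pairwise alignment.

Coordinates are 0-based half-open on the forward strand throughout the library;
GFF3 I/O converts to/from the 1-based inclusive interchange convention.  mRNA
order of exons is taken from an explicit ``exon_number`` attribute, never from
genomic order, because trans-spliced exons are not collinear.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "AnnotationError",
    "CoordinateError",
    "FrameError",
    "SequenceRecord",
    "ExonAnnotation",
    "Intron",
    "GeneModel",
    "revcomp",
    "derive_introns",
    "extract_mature_cds",
    "translate",
    "global_align",
    "load_locus",
    "save_locus",
]

_DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AnnotationError(ValueError):
    """Gene annotation violates the model invariants."""


class CoordinateError(ValueError):
    """An interval is malformed or falls outside its sequence."""


class FrameError(ValueError):
    """A coding sequence length is not a multiple of three."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence, optionally circular."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty sequence")
        seq = self.seq.upper()
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"non-DNA characters in {self.id!r}: {sorted(bad)}")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps the origin only for circular records."""
        if start < 0 or end < start:
            raise CoordinateError(f"bad interval [{start}, {end})")
        if end <= len(self.seq):
            return self.seq[start:end]
        if not self.circular:
            raise CoordinateError(
                f"interval [{start}, {end}) exceeds linear sequence of length {len(self.seq)}"
            )
        doubled = self.seq + self.seq
        if end - start > len(self.seq):
            raise CoordinateError("interval longer than circular sequence")
        return doubled[start:end]


@dataclass(frozen=True)
class ExonAnnotation:
    """One exon: genomic interval, strand and its rank in the mature mRNA."""

    exon_id: str
    start: int
    end: int
    strand: str
    mrna_order: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise CoordinateError(
                f"exon {self.exon_id!r}: bad interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"exon {self.exon_id!r}: strand must be + or -")
        if self.mrna_order < 1:
            raise AnnotationError(f"exon {self.exon_id!r}: mrna_order must be >= 1")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Intron:
    """A derived intron.

    ``cis`` introns carry a genomic interval on the shared strand of their
    neighbouring exons; ``trans-junction`` markers join exons from separate
    precursor molecules and carry no interval (start/end are None).
    """

    intron_id: str
    kind: str  # "cis" | "trans-junction"
    upstream_exon_id: str
    downstream_exon_id: str
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cis", "trans-junction"):
            raise AnnotationError(f"unknown intron kind {self.kind!r}")
        if self.kind == "cis":
            if self.start is None or self.end is None or self.end <= self.start:
                raise CoordinateError(f"cis intron {self.intron_id!r} needs end > start")
            if self.strand not in ("+", "-"):
                raise AnnotationError(f"cis intron {self.intron_id!r} needs a strand")
        elif self.start is not None or self.end is not None:
            raise AnnotationError("trans-junction carries no genomic interval")

    def __len__(self) -> int:
        if self.kind != "cis":
            return 0
        return self.end - self.start


@dataclass
class GeneModel:
    """A (possibly trans-spliced) gene: ordered exons plus derived introns."""

    gene_id: str
    exons: list[ExonAnnotation]
    genome_id: str
    introns: list[Intron] = field(default_factory=list)
    complete: bool = True

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id!r} has no exons")
        orders = sorted(e.mrna_order for e in self.exons)
        if orders != list(range(1, len(self.exons) + 1)):
            raise AnnotationError(
                f"gene {self.gene_id!r}: mrna_order values must be a contiguous 1..n permutation"
            )
        by_pos = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_pos, by_pos[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"gene {self.gene_id!r}: exons {a.exon_id!r} and {b.exon_id!r} overlap"
                )
        self.exons = sorted(self.exons, key=lambda e: e.mrna_order)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_by_id(self, exon_id: str) -> ExonAnnotation:
        for exon in self.exons:
            if exon.exon_id == exon_id:
                return exon
        raise KeyError(exon_id)

    def intron_by_id(self, intron_id: str) -> Intron:
        for intron in self.introns:
            if intron.intron_id == intron_id:
                return intron
        raise KeyError(intron_id)

    def cds_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def cds_offsets(self) -> dict[str, int]:
        """CDS start offset of each exon, keyed by exon_id, in mRNA order."""
        offsets: dict[str, int] = {}
        pos = 0
        for exon in self.exons:
            offsets[exon.exon_id] = pos
            pos += len(exon)
        return offsets

    def with_introns(self, genome: SequenceRecord) -> "GeneModel":
        model = replace(self)
        model.introns = derive_introns(model, genome)
        return model


def derive_introns(model: GeneModel, genome: SequenceRecord | None = None) -> list[Intron]:
    """Introns between mRNA-consecutive exons.

    Same-strand neighbours with a positive genomic gap (in the direction of
    transcription) yield a cis intron spanning the gap; any other configuration
    is a trans-junction.  A zero-length gap between same-strand neighbours is an
    annotation error: abutting exons must be merged.
    """
    introns: list[Intron] = []
    exons = sorted(model.exons, key=lambda e: e.mrna_order)
    for i, (a, b) in enumerate(zip(exons, exons[1:]), start=1):
        cis = False
        if a.strand == b.strand:
            if a.strand == "+":
                gap_start, gap_end = a.end, b.start
            else:
                gap_start, gap_end = b.end, a.start
            if gap_start == gap_end:
                raise AnnotationError(
                    f"exons {a.exon_id!r} and {b.exon_id!r} abut with no intron; merge them"
                )
            cis = gap_start < gap_end
        if cis:
            if genome is not None and gap_end > len(genome) and not genome.circular:
                raise CoordinateError(f"intron [{gap_start}, {gap_end}) exceeds genome")
            introns.append(
                Intron(
                    intron_id=f"intron_{i}",
                    kind="cis",
                    upstream_exon_id=a.exon_id,
                    downstream_exon_id=b.exon_id,
                    start=gap_start,
                    end=gap_end,
                    strand=a.strand,
                )
            )
        else:
            introns.append(
                Intron(
                    intron_id=f"trans_{i}",
                    kind="trans-junction",
                    upstream_exon_id=a.exon_id,
                    downstream_exon_id=b.exon_id,
                )
            )
    return introns


def exon_sequence(genome: SequenceRecord, exon: ExonAnnotation) -> str:
    """Exon sequence in mRNA sense (reverse-complemented for minus strand)."""
    raw = genome.fetch(exon.start, exon.end)
    return revcomp(raw) if exon.strand == "-" else raw


def extract_mature_cds(genome: SequenceRecord, model: GeneModel) -> str:
    """Concatenation of exon sequences in mRNA order, strand-resolved."""
    parts = []
    for exon in sorted(model.exons, key=lambda e: e.mrna_order):
        seq = exon_sequence(genome, exon)
        if "N" in seq:
            raise AnnotationError(f"exon {exon.exon_id!r} contains N")
        parts.append(seq)
    return "".join(parts)


def translate(cds: str, code: int = 4) -> str:
    """Translate a CDS under the given genetic code (default: table 4).

    Under table 4 (mold/protozoan/coelenterate mitochondrial), TGA encodes
    tryptophan; stops are rendered as ``*``.
    """
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not a multiple of 3")
    if not cds:
        return ""
    return str(Seq(cds).translate(table=code))


def global_align(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> tuple[str, str, int, float]:
    """Classical Needleman-Wunsch global alignment with linear gap cost.

    Returns ``(aligned_a, aligned_b, score, percent_identity)`` where percent
    identity is identical columns over alignment length x 100.  Traceback ties
    are broken diagonal > up (gap in b) > left (gap in a), which makes the
    reported alignment deterministic; the score is tie-free by construction.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    n, m = len(a), len(b)
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    score = np.empty((n + 1, m + 1), dtype=np.int64)
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    sub = np.where(arr_a[:, None] == arr_b[None, :], match, mismatch)
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + gap
        row = score[i]
        prev = row[0]
        best_du = np.maximum(diag, up)
        for j in range(1, m + 1):
            prev = max(best_du[j - 1], prev + gap)
            row[j] = prev
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    identical = sum(x == y for x, y in zip(aligned_a, aligned_b))
    pct = 100.0 * identical / len(aligned_a)
    return aligned_a, aligned_b, int(score[n, m]), pct


# ---------------------------------------------------------------------------
# FASTA + GFF3 I/O
# ---------------------------------------------------------------------------

_GFF_ESCAPES = {"%": "%25", ";": "%3B", "=": "%3D", ",": "%2C", "\t": "%09"}


def _gff_escape(value: str) -> str:
    for raw, esc in _GFF_ESCAPES.items():
        value = value.replace(raw, esc)
    return value


def _gff_unescape(value: str) -> str:
    return re.sub("%([0-9A-Fa-f]{2})", lambda m: chr(int(m.group(1), 16)), value)


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = _gff_unescape(value.strip())
    return attrs


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA records; a ``circular=true`` token in the description is honoured."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circular = "circular=true" in rec.description.lower()
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), circular=circular))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            circ = " circular=true" if getattr(rec, "circular", False) else ""
            fh.write(f">{rec.id}{circ}\n")
            seq = rec.seq
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_locus(fasta_path, gff_path) -> tuple[SequenceRecord, GeneModel]:
    """Load a single-contig genome and its fragmented-gene exon annotation.

    The GFF3 must carry ``exon`` features with ``gene_id``, ``exon_id`` and
    ``exon_number`` attributes; 1-based inclusive coordinates are converted to
    0-based half-open.  Annotations wrapping the origin of a circular genome
    are rejected.
    """
    genome = read_fasta(fasta_path)[0]
    exons: list[ExonAnnotation] = []
    gene_id = None
    with open(gff_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(f"malformed GFF line: {line!r}")
            seqid, _source, ftype, start1, end1, _score, strand, _frame, attr_text = cols
            if ftype != "exon":
                continue
            if seqid != genome.id:
                raise AnnotationError(f"GFF seqid {seqid!r} does not match genome {genome.id!r}")
            start1, end1 = int(start1), int(end1)
            if end1 < start1:
                raise CoordinateError(f"GFF exon with end < start: {line!r}")
            start, end = start1 - 1, end1
            if end > len(genome):
                raise CoordinateError(
                    f"exon [{start1}, {end1}] exceeds genome length {len(genome)}"
                )
            attrs = _parse_attributes(attr_text)
            for key in ("gene_id", "exon_id", "exon_number"):
                if key not in attrs:
                    raise AnnotationError(f"GFF exon missing {key!r} attribute")
            if gene_id is None:
                gene_id = attrs["gene_id"]
            elif attrs["gene_id"] != gene_id:
                raise AnnotationError("multiple gene_id values in annotation")
            exons.append(
                ExonAnnotation(
                    exon_id=attrs["exon_id"],
                    start=start,
                    end=end,
                    strand=strand,
                    mrna_order=int(attrs["exon_number"]),
                )
            )
    if not exons:
        raise AnnotationError(f"no exon features in {gff_path}")
    model = GeneModel(gene_id=gene_id, exons=exons, genome_id=genome.id)
    model.introns = derive_introns(model, genome)
    return genome, model


def save_locus(genome: SequenceRecord, model: GeneModel, fasta_path, gff_path) -> None:
    """Write the locus back out as FASTA + GFF3 (inverse of :func:`load_locus`)."""
    write_fasta([genome], fasta_path)
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for exon in sorted(model.exons, key=lambda e: e.mrna_order):
            attrs = (
                f"gene_id={_gff_escape(model.gene_id)};"
                f"exon_id={_gff_escape(exon.exon_id)};"
                f"exon_number={exon.mrna_order}"
            )
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "microexon",
                        "exon",
                        str(exon.start + 1),
                        str(exon.end),
                        ".",
                        exon.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
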