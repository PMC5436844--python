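"""Annotation-constrained micro-exon site scanning and cross-species reporting.

Without RNA-seq evidence, a candidate micro-exon site in a related genome is a
position inside an annotated intron whose sequence context matches the splice
motif (GG / candidate base / AA in pre-mRNA orientation) *and* whose
hypothetical insertion -- substituting for the terminal base the current
annotation assigns to the upstream exon -- preserves the reading frame, keeps
the conserved histidine codon, and leaves the upstream exon ending in T.  The
scan is intron-constrained rather than genome-wide: a 5-mer motif alone is
not specific at genome scale, and the biological claim is about a particular
intron.

Reported positions are 1-based (GenBank convention); internal arithmetic is
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

from microexon.genome_model import (
    GeneModel,
    SequenceRecord,
    extract_mature_cds,
    global_align,
    revcomp,
    translate,
)
from microexon.inference import MicroExonCall, validate_call

__all__ = [
    "CandidateSite",
    "SubstitutionRecord",
    "scan_intron_for_site",
    "conservation_report",
    "exon_identity_stats",
]


@dataclass(frozen=True)
class CandidateSite:
    """A validating motif hit inside an annotated intron."""

    position: int  # 0-based genomic position of the candidate micro-exon base
    base: str  # in mRNA sense
    context: str  # motif context in pre-mRNA orientation
    intron_id: str
    frame_preserved: bool
    conserved_codon: bool
    upstream_terminal_t: bool
    motif_match: bool

    @property
    def position_1based(self) -> int:
        return self.position + 1


@dataclass(frozen=True)
class SubstitutionRecord:
    """A single-nucleotide difference between two concatenated exon sets."""

    cds_position: int  # 0-based
    exon_id: str
    codon_position: int  # 1, 2 or 3
    base_a: str
    base_b: str
    synonymous: bool  # under genetic code 4, holding the partner codon fixed


def scan_intron_for_site(
    genome: SequenceRecord,
    model: GeneModel,
    intron_id: str,
    motif: tuple[str, str, str] = ("GG", "C", "AA"),
) -> list[CandidateSite]:
    """All validating motif positions inside one annotated cis intron.

    A position validates when the pre-mRNA context is ``motif`` and the
    hypothetical one-base call (replacing the upstream exon's terminal base)
    passes the frame, conserved-codon and terminal-T checks.  The scan does
    not assume the motif occurs uniquely; every validating position is
    returned, sorted.
    """
    intron = model.intron_by_id(intron_id)
    if intron.kind != "cis":
        raise ValueError(f"{intron_id!r} is not a cis intron")
    five, base, three = motif
    target = five + base + three
    n5, nb = len(five), len(base)
    sites: list[CandidateSite] = []
    window_len = len(target)
    for w0 in range(intron.start, intron.end - window_len + 1):
        window = genome.seq[w0 : w0 + window_len]
        if intron.strand == "+":
            if window != target:
                continue
            pos = w0 + n5
            upstream_iv = (intron.start - 1, pos)
            downstream_iv = (pos + nb, intron.end)
        else:
            if window != revcomp(target):
                continue
            # in mRNA sense the candidate base is at the centre of the window
            pos = w0 + len(three)
            upstream_iv = (pos + nb, intron.end + 1)
            downstream_iv = (intron.start, pos)
        call = MicroExonCall(
            start=pos,
            end=pos + nb,
            seq=base,
            strand=intron.strand,
            intron_id=intron.intron_id,
            upstream_intron=upstream_iv,
            downstream_intron=downstream_iv,
        )
        validated = validate_call(call, genome, model)
        if (
            validated.frame_preserved
            and validated.conserved_codon
            and validated.upstream_terminal_t
        ):
            sites.append(
                CandidateSite(
                    position=pos,
                    base=base,
                    context=f"{five}/{base}/{three}",
                    intron_id=intron.intron_id,
                    frame_preserved=validated.frame_preserved,
                    conserved_codon=validated.conserved_codon,
                    upstream_terminal_t=validated.upstream_terminal_t,
                    motif_match=validated.motif_match,
                )
            )
    return sorted(sites, key=lambda s: s.position)


def conservation_report(
    loci: list[tuple[SequenceRecord, GeneModel, str]],
    motif: tuple[str, str, str] = ("GG", "C", "AA"),
    intron_id: str | None = None,
) -> tuple[list[dict], list[dict]]:
    """Per-species candidate-site presence plus pairwise intron identity.

    Scans the named intron (or every cis intron) of each locus.  A locus
    missing the target intron is flagged in its row, not fatal.  For loci
    where a site is found, the host introns are globally aligned pairwise and
    their percent identity reported as context.
    """
    if not loci:
        raise ValueError("conservation_report needs at least one locus")
    rows: list[dict] = []
    host_introns: dict[str, str] = {}
    for genome, model, label in loci:
        intron_ids = (
            [intron_id]
            if intron_id is not None
            else [i.intron_id for i in model.introns if i.kind == "cis"]
        )
        sites: list[CandidateSite] = []
        flagged = None
        for iid in intron_ids:
            try:
                sites.extend(scan_intron_for_site(genome, model, iid, motif))
            except KeyError:
                flagged = f"intron {iid!r} not annotated"
        if flagged and not sites:
            rows.append({"species": label, "found": False, "note": flagged})
            continue
        if not sites:
            rows.append(
                {
                    "species": label,
                    "found": False,
                    "note": "no validating motif site",
                }
            )
            continue
        site = sites[0]
        intron = model.intron_by_id(site.intron_id)
        seq = genome.fetch(intron.start, intron.end)
        if intron.strand == "-":
            seq = revcomp(seq)
        host_introns[label] = seq
        rows.append(
            {
                "species": label,
                "found": True,
                "position_1based": site.position_1based,
                "intron_id": site.intron_id,
                "context": site.context,
                "n_sites": len(sites),
            }
        )
    pairwise: list[dict] = []
    labels = list(host_introns)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            _, _, _, pct = global_align(host_introns[a], host_introns[b])
            pairwise.append({"a": a, "b": b, "intron_identity_pct": round(pct, 1)})
    return rows, pairwise


def exon_identity_stats(
    cds_a: str,
    cds_b: str,
    model: GeneModel,
) -> tuple[float, list[SubstitutionRecord]]:
    """Percent identity and per-substitution annotation for two concatenated
    exon sets of the same gene model.

    Inputs must be equal length, or alignable without gaps; a gapped alignment
    means the exon models disagree and is refused.  Synonymy is evaluated
    under genetic code 4 by substituting the partner base into the first
    sequence's codon.  Symmetric in its two inputs up to the a/b base labels.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        aligned_a, aligned_b, _, _ = global_align(cds_a, cds_b)
        if "-" in aligned_a or "-" in aligned_b:
            raise ValueError(
                "sequences require gaps to align; the exon models disagree"
            )
    exon_of: list[tuple[int, str]] = []
    pos = 0
    for exon in sorted(model.exons, key=lambda e: e.mrna_order):
        exon_of.append((pos, exon.exon_id))
        pos += len(exon)
    if pos != len(cds_a):
        raise ValueError("CDS length does not match the gene model")

    def exon_id_at(i: int) -> str:
        out = exon_of[0][1]
        for off, eid in exon_of:
            if off <= i:
                out = eid
        return out

    records: list[SubstitutionRecord] = []
    for i, (a, b) in enumerate(zip(cds_a, cds_b)):
        if a == b:
            continue
        k = i // 3
        codon_a = cds_a[3 * k : 3 * k + 3]
        codon_sub = codon_a[: i % 3] + b + codon_a[i % 3 + 1 :]
        synonymous = translate(codon_a) == translate(codon_sub)
        records.append(
            SubstitutionRecord(
                cds_position=i,
                exon_id=exon_id_at(i),
                codon_position=i % 3 + 1,
                base_a=a,
                base_b=b,
                synonymous=synonymous,
            )
        )
    pct = 100.0 * (len(cds_a) - len(records)) / len(cds_a)
    return pct, records
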