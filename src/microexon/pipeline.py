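"""End-to-end orchestration: simulate or load inputs, map, classify, assemble,
infer, validate, re-annotate, decide, report.

A run is configured by a plain dict (or YAML file): either a ``simulate``
block (self-contained demo on a synthetic locus) or explicit ``genome`` /
``annotation`` / ``reads_1`` / ``reads_2`` paths.  All stage outputs land in
the output directory; the JSON report embeds input digests and the full
parameter snapshot so that report + inputs + seed reproduce the run.
Timestamps go to the log only, never into the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from microexon.assembler import (
    AssemblyParams,
    ClassifyParams,
    LocusProvenance,
    ReadClass,
    assemble_intermediates,
    classify_read,
    compute_coverage,
)
from microexon.genome_model import (
    GeneModel,
    extract_mature_cds,
    load_locus,
    revcomp,
    save_locus,
)
from microexon.inference import (
    decide_hypothesis,
    infer_microexon,
    reannotate,
    validate_call,
)
from microexon.mapper import MapParams, ReferenceIndex, map_read, write_alignments_tsv
from microexon.synthetic import (
    LocusConfig,
    build_transcript_set,
    cds_reference_id,
    generate_locus,
    naive_model,
    simulate_reads,
    write_fastq_pair,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "PipelineParams", "PipelineReport", "run_all", "load_config"]


class PipelineError(RuntimeError):
    """The pipeline cannot run with the given configuration."""


@dataclass(frozen=True)
class PipelineParams:
    mapping: MapParams = MapParams()
    classify: ClassifyParams = ClassifyParams()
    assembly: AssemblyParams = AssemblyParams()
    max_micro_exon_len: int = 30
    min_junction: int = 3
    # focal-site variant calling: a base observation must reach both an
    # absolute count and a fraction of the site depth to be counted as a
    # transcript population rather than sequencing noise (phantom bases arrive
    # at a rate of about error_rate/3 per alternative base per read)
    min_variant_reads: int = 2
    min_variant_fraction: float = 0.05
    min_variant_freq: float = 0.5
    min_variant_depth: int = 5


@dataclass
class PipelineReport:
    inputs: dict
    parameters: dict
    seed: int | None
    world: str | None
    n_pairs: int
    class_counts: dict
    cds_coverage_mean: float
    gene_coverage_mean: float
    contigs: list
    half_supported: list
    calls: list
    focal_site: int | None
    variant_counts: dict
    decision: dict
    reannotated_exon_count: int | None
    outputs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PipelineError(f"configuration in {path} is not a mapping")
    return config


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_fastq(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def _params_from_config(config: dict) -> PipelineParams:
    params = PipelineParams()
    overrides = config.get("params", {})
    known = {"max_micro_exon_len", "min_junction", "min_variant_reads",
             "min_variant_fraction", "min_variant_freq", "min_variant_depth"}
    bad = set(overrides) - known - {"mapping", "classify", "assembly"}
    if bad:
        raise PipelineError(f"unknown parameter overrides: {sorted(bad)}")
    simple = {k: v for k, v in overrides.items() if k in known}
    nested = {}
    for key, cls in (("mapping", MapParams), ("classify", ClassifyParams),
                     ("assembly", AssemblyParams)):
        if key in overrides:
            nested[key] = cls(**overrides[key])
    return replace(params, **simple, **nested)


def _prepare_inputs(config: dict, outdir: Path):
    """Returns (genome, input_model, pairs, inputs_manifest, world, seed)."""
    seed = config.get("seed")
    if "simulate" in config:
        sim = dict(config["simulate"])
        world = sim.pop("world", "micro_exon")
        coverage = sim.pop("coverage", 40)
        error_rate = sim.pop("error_rate", 0.005)
        read_len = sim.pop("read_len", 76)
        insert_mean = sim.pop("insert_mean", 300)
        insert_sd = sim.pop("insert_sd", 30)
        if seed is not None:
            sim["seed"] = seed
        locus_config = LocusConfig(**sim)
        genome, model, truth = generate_locus(locus_config)
        input_model = naive_model(model, truth)
        transcripts = build_transcript_set(genome, model, truth, world=world)
        read_seed = (locus_config.seed + 1_000_003) % 2**31
        pairs = simulate_reads(
            transcripts,
            genome,
            input_model,
            truth,
            read_len=read_len,
            insert_mean=insert_mean,
            insert_sd=insert_sd,
            coverage=coverage,
            error_rate=error_rate,
            seed=read_seed,
        )
        sim_dir = outdir / "sim"
        sim_dir.mkdir(parents=True, exist_ok=True)
        save_locus(genome, input_model, sim_dir / "genome.fa", sim_dir / "annotation.gff3")
        save_locus(genome, model, sim_dir / "genome.fa", sim_dir / "annotation_true.gff3")
        write_fastq_pair(pairs, sim_dir / "reads_1.fastq", sim_dir / "reads_2.fastq")
        truth.to_json(sim_dir / "truth.json")
        manifest = {
            "simulate": {"world": world, "coverage": coverage, "error_rate": error_rate,
                         "read_len": read_len, "locus_seed": locus_config.seed,
                         "read_seed": read_seed},
            "genome": str(sim_dir / "genome.fa"),
            "annotation": str(sim_dir / "annotation.gff3"),
        }
        return genome, input_model, pairs, manifest, world, locus_config.seed
    for key in ("genome", "annotation", "reads_1", "reads_2"):
        if key not in config:
            raise PipelineError(f"configuration misses required input {key!r}")
        if not Path(config[key]).exists():
            raise PipelineError(f"input file not found: {config[key]}")
    genome, input_model = load_locus(config["genome"], config["annotation"])
    mates1 = _read_fastq(config["reads_1"])
    mates2 = _read_fastq(config["reads_2"])
    if len(mates1) != len(mates2):
        raise PipelineError("mate files differ in read count")
    pairs = [(id1, s1, s2) for (id1, s1), (_id2, s2) in zip(mates1, mates2)]
    manifest = {
        key: {"path": str(config[key]), "sha256": _sha256(config[key])}
        for key in ("genome", "annotation", "reads_1", "reads_2")
    }
    return genome, input_model, pairs, manifest, None, seed


def _detect_focal_site(base_counts: dict[int, Counter], cds: str, params: PipelineParams):
    """CDS position where spliced reads consistently disagree with the reference."""
    best_pos, best_alt = None, 0
    for pos, counts in base_counts.items():
        depth = sum(counts.values())
        if depth < params.min_variant_depth:
            continue
        alt = depth - counts.get(cds[pos], 0)
        if alt > best_alt and alt / depth >= params.min_variant_freq:
            best_pos, best_alt = pos, alt
    return best_pos


def run_all(config: dict, upto: str = "report") -> PipelineReport:
    """Execute the pipeline: map -> classify -> assemble -> infer -> validate ->
    reannotate -> decide -> report.

    ``upto`` truncates the run after a named stage ("map", "classify",
    "assemble", "infer"); later report fields stay empty.
    """
    stages = ["map", "classify", "assemble", "infer", "report"]
    if upto not in stages:
        raise PipelineError(f"unknown stage {upto!r}")
    outdir = Path(config.get("outdir", "microexon_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    params = _params_from_config(config)
    genome, input_model, pairs, manifest, world, seed = _prepare_inputs(config, outdir)
    cds = extract_mature_cds(genome, input_model)
    cds_id = cds_reference_id(input_model)
    prov = LocusProvenance(input_model, len(genome), cds_id=cds_id)
    genome_index = ReferenceIndex(genome, k=params.mapping.k)
    cds_index = ReferenceIndex(cds, k=params.mapping.k, name=cds_id)

    # --- map (CDS first, then the genomic locus) ---------------------------
    reads: list[tuple[str, str]] = []
    for read_id, seq1, seq2 in pairs:
        reads.append((f"{read_id}/1", seq1))
        reads.append((f"{read_id}/2", seq2))
    placements: dict[str, list] = {}
    for read_id, seq in reads:
        alns = map_read(seq, cds_index, params.mapping, read_id=read_id)
        alns += map_read(seq, genome_index, params.mapping, read_id=read_id)
        placements[read_id] = alns
    report = PipelineReport(
        inputs=manifest,
        parameters={
            "mapping": asdict(params.mapping),
            "classify": asdict(params.classify),
            "assembly": asdict(params.assembly),
            "max_micro_exon_len": params.max_micro_exon_len,
            "min_junction": params.min_junction,
            "min_variant_reads": params.min_variant_reads,
            "min_variant_freq": params.min_variant_freq,
            "min_variant_depth": params.min_variant_depth,
        },
        seed=seed,
        world=world,
        n_pairs=len(pairs),
        class_counts={},
        cds_coverage_mean=0.0,
        gene_coverage_mean=0.0,
        contigs=[],
        half_supported=[],
        calls=[],
        focal_site=None,
        variant_counts={},
        decision={},
        reannotated_exon_count=None,
    )
    best_alignments = [
        aln for alns in placements.values() if alns
        for aln in alns[:1]
    ]
    write_alignments_tsv(best_alignments, outdir / "alignments.tsv")
    report.outputs["alignments"] = str(outdir / "alignments.tsv")
    if upto == "map":
        report.to_json(outdir / "report.json")
        return report

    # --- classify -----------------------------------------------------------
    classes: list[ReadClass] = []
    seq_of_read = dict(reads)
    for read_id, _seq in reads:
        rc = classify_read(
            read_id, placements[read_id], prov, params.classify, read_seq=seq_of_read[read_id]
        )
        classes.append(rc)
    class_counts = Counter(rc.label for rc in classes)
    report.class_counts = dict(sorted(class_counts.items()))
    with open(outdir / "classes.tsv", "w") as fh:
        fh.write("read_id\tclass\treference\tscore\n")
        for rc in classes:
            ref = rc.alignment.reference_id if rc.alignment else "."
            score = rc.alignment.score if rc.alignment else "."
            fh.write(f"{rc.read_id}\t{rc.label}\t{ref}\t{score}\n")
    report.outputs["classes"] = str(outdir / "classes.tsv")

    mature = [rc for rc in classes if rc.label == "mature"]
    cds_alns = [rc.alignment for rc in mature if rc.alignment.reference_id == cds_id]
    if cds_alns:
        _, report.cds_coverage_mean = compute_coverage(cds_alns, 0, len(cds))
    gene_span = (
        min(e.start for e in input_model.exons),
        max(e.end for e in input_model.exons),
    )
    genome_alns = [
        rc.alignment
        for rc in classes
        if rc.alignment is not None and rc.alignment.reference_id == genome.id
    ]
    if genome_alns:
        _, report.gene_coverage_mean = compute_coverage(genome_alns, *gene_span)
    if upto == "classify":
        report.to_json(outdir / "report.json")
        return report

    # --- assemble intermediate-stage reads ----------------------------------
    intermediates = [rc for rc in classes if rc.label == "intermediate"]
    contigs = assemble_intermediates(intermediates, genome, prov, params.assembly)
    with open(outdir / "contigs.fa", "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.contig_id} blocks={contig.blocks}\n{contig.seq}\n")
    report.outputs["contigs"] = str(outdir / "contigs.fa")
    report.contigs = [
        {
            "contig_id": c.contig_id,
            "length": len(c.seq),
            "blocks": c.blocks,
            "junctions": c.junctions,
            "n_reads": len(c.read_ids),
            "mean_coverage": round(c.mean_coverage, 2),
            "provenance": c.provenance,
        }
        for c in contigs
    ]
    if upto == "assemble":
        report.to_json(outdir / "report.json")
        return report

    # --- infer, validate, re-annotate ---------------------------------------
    calls, half_supported = infer_microexon(
        contigs, input_model, genome, params.max_micro_exon_len
    )
    calls = [validate_call(call, genome, input_model) for call in calls]
    report.half_supported = half_supported
    report.calls = [
        {
            "start": call.start,
            "end": call.end,
            "position_1based": call.start + 1,
            "length": len(call),
            "seq": call.seq,
            "strand": call.strand,
            "intron_id": call.intron_id,
            "upstream_intron": list(call.upstream_intron),
            "downstream_intron": list(call.downstream_intron),
            "w_contig": call.w_contig_id,
            "x_contig": call.x_contig_id,
            "frame_preserved": call.frame_preserved,
            "conserved_codon": call.conserved_codon,
            "upstream_terminal_t": call.upstream_terminal_t,
            "motif_match": call.motif_match,
            "validated": call.validated,
        }
        for call in calls
    ]
    new_model: GeneModel | None = None
    focal_site = None
    if calls:
        new_model = reannotate(input_model, calls[0], genome)
        save_locus(genome, new_model, outdir / "genome.fa", outdir / "reannotated.gff3")
        report.outputs["reannotated"] = str(outdir / "reannotated.gff3")
        report.reannotated_exon_count = new_model.n_exons
        micro_id = f"microexon_{calls[0].start}"
        focal_site = new_model.cds_offsets()[micro_id]
    if upto == "infer":
        report.to_json(outdir / "report.json")
        return report

    # --- focal-site variant counts and the decision -------------------------
    base_counts: dict[int, Counter] = {}
    for rc in mature:
        aln = rc.alignment
        if aln.reference_id != cds_id:
            continue
        oriented = rc.read_seq if aln.strand == "+" else revcomp(rc.read_seq)
        for seg in aln.segments:
            for off in range(len(seg)):
                pos = seg.ref_start + off
                base_counts.setdefault(pos, Counter())[oriented[seg.read_start + off]] += 1
    if focal_site is None:
        focal_site = _detect_focal_site(base_counts, cds, params)
    variant_counts = {"altered": 0, "unaltered": 0}
    site_base_counts: dict[str, int] = {}
    if focal_site is not None and focal_site in base_counts:
        counts = base_counts[focal_site]
        ref_base = cds[focal_site]
        depth = sum(counts.values())
        floor = max(params.min_variant_reads, int(params.min_variant_fraction * depth))
        unaltered = counts.get(ref_base, 0)
        variant_counts["unaltered"] = unaltered if unaltered >= floor else 0
        alt = {b: c for b, c in counts.items() if b != ref_base and c >= floor}
        if alt:
            variant_counts["altered"] = max(alt.values())
        site_base_counts = dict(sorted(counts.items()))
    report.focal_site = focal_site
    report.variant_counts = {**variant_counts, "site_base_counts": site_base_counts}
    decision = decide_hypothesis(
        report.class_counts,
        variant_counts,
        min_junction=params.min_junction,
    )
    report.decision = asdict(decision)
    report.to_json(outdir / "report.json")
    report.outputs["report"] = str(outdir / "report.json")
    return report


def _revcomp(seq: str) -> str:
    from microexon.genome_model import revcomp

    return revcomp(seq)
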