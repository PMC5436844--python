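#!/usr/bin/env python
"""Generate the default synthetic locus and summarise its architecture.

Builds the nine-exon, trans-spliced gene with its planted single-base micro
exon, writes the locus (FASTA + both annotations) under scratch/, and a small
structural summary table under results/.
"""

import json
from pathlib import Path

from microexon.genome_model import extract_mature_cds, save_locus, translate
from microexon.synthetic import LocusConfig, generate_locus, naive_model

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis" / "locus"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    config = LocusConfig()  # seed 42, 1,605-nt CDS, 11-nt exon 4, 1-nt exon 7
    genome, model, truth = generate_locus(config)
    naive = naive_model(model, truth)
    save_locus(genome, model, SCRATCH / "genome.fa", SCRATCH / "annotation_true.gff3")
    save_locus(genome, naive, SCRATCH / "genome.fa", SCRATCH / "annotation_naive.gff3")
    cds = extract_mature_cds(genome, model)
    summary = {
        "seed": config.seed,
        "genome_length": len(genome),
        "cds_length": len(cds),
        "n_exons_true": model.n_exons,
        "n_exons_naive": naive.n_exons,
        "exons": [
            {"id": e.exon_id, "start": e.start, "end": e.end, "strand": e.strand,
             "length": len(e), "mrna_order": e.mrna_order}
            for e in model.exons
        ],
        "cis_introns": sum(1 for i in model.introns if i.kind == "cis"),
        "trans_junctions": sum(1 for i in model.introns if i.kind == "trans-junction"),
        "micro_exon": {"interval": list(truth.micro_exon), "seq": truth.micro_exon_seq,
                       "strand": truth.strand, "cds_offset": truth.cds_offset},
        "focal_codon": cds[truth.cds_offset : truth.cds_offset + 3],
        "focal_amino_acid": translate(cds)[truth.cds_offset // 3],
    }
    with open(RESULTS / "locus_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(f"locus: {len(genome)} bp genome, {model.n_exons} exons "
          f"({naive.n_exons} in the pre-discovery annotation), CDS {len(cds)} nt")
    print(f"micro exon: {truth.micro_exon_seq!r} at {truth.micro_exon}, "
          f"codon {summary['focal_codon']} -> {summary['focal_amino_acid']}")
    print(f"wrote {RESULTS / 'locus_summary.json'} and locus files under {SCRATCH}")


if __name__ == "__main__":
    main()
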