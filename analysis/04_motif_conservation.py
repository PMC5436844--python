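#!/usr/bin/env python
"""Cross-species motif conservation scan.

Builds a five-locus panel (independent exon/intron backgrounds, shared splice
motif context), scans each locus's annotated introns for validating GG/C/AA
micro-exon sites without using any RNA-seq, and reports per-species presence
plus pairwise identity of the host introns.
"""

import csv
from pathlib import Path

from microexon.conservation import conservation_report
from microexon.synthetic import LocusConfig, make_species_panel, naive_model

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    panel = make_species_panel(LocusConfig(seed=42), n=5)
    loci = [(genome, naive_model(model, truth), label) for genome, model, truth, label in panel]
    rows, pairwise = conservation_report(loci)
    with open(RESULTS / "conservation.tsv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["species", "found", "position_1based", "intron_id", "context",
                        "n_sites", "note"],
            delimiter="\t",
        )
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
    with open(RESULTS / "conservation_pairwise.tsv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["a", "b", "intron_identity_pct"], delimiter="\t")
        writer.writeheader()
        for pair in pairwise:
            writer.writerow(pair)
    found = sum(1 for r in rows if r["found"])
    identities = [p["intron_identity_pct"] for p in pairwise]
    print(f"motif site found in {found}/{len(rows)} species")
    for row in rows:
        print(f"  {row['species']}: position {row.get('position_1based')} "
              f"in {row.get('intron_id')} ({row.get('context')})")
    print(f"pairwise host-intron identity: {min(identities):.1f}-{max(identities):.1f}% "
          "(low despite the conserved motif)")
    print(f"wrote {RESULTS / 'conservation.tsv'} and conservation_pairwise.tsv")


if __name__ == "__main__":
    main()
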