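#!/usr/bin/env python
"""Exon-identity statistics on a constructed divergent pair.

Builds a partner CDS differing from the default locus's 1,605-nt concatenated
exons by exactly five third-position synonymous substitutions (three in exon
2, two in exon 9) and verifies that the per-substitution annotation recovers
that pattern with 99.7% overall identity.
"""

import csv
from pathlib import Path

from microexon.conservation import exon_identity_stats
from microexon.synthetic import LocusConfig, generate_locus, make_divergent_cds

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    genome, model, _ = generate_locus(LocusConfig(seed=42))
    cds_a, cds_b = make_divergent_cds(genome, model, seed=42)
    pct, records = exon_identity_stats(cds_a, cds_b, model)
    with open(RESULTS / "exon_identity.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["cds_position", "exon_id", "codon_position", "base_a",
                         "base_b", "synonymous"])
        for r in records:
            writer.writerow([r.cds_position, r.exon_id, r.codon_position, r.base_a,
                             r.base_b, r.synonymous])
    print(f"identity over {len(cds_a)} nt: {pct:.2f}% (rounds to {round(pct, 1)})")
    by_exon: dict[str, int] = {}
    for r in records:
        by_exon[r.exon_id] = by_exon.get(r.exon_id, 0) + 1
    print(f"substitutions per exon: {by_exon}; "
          f"all third-position: {all(r.codon_position == 3 for r in records)}; "
          f"all synonymous: {all(r.synonymous for r in records)}")
    print(f"wrote {RESULTS / 'exon_identity.tsv'}")


if __name__ == "__main__":
    main()
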