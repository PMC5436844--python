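# Methods

## The inference in one paragraph

A single-base difference between a genome and its mature mRNA, inside an
essential codon, can be explained by RNA editing or by an unannotated micro
exon. The two hypotheses make opposite read-level predictions. If the base is
edited after splicing, some spliced reads should still carry the genomic base
at the site (the pre-editing transcript, called Z here), and no read should
retain intron sequence adjacent to the site beyond normal precursor reads. If
the base is a micro exon, no spliced read ever carries the genomic base, and
two distinct intermediate transcript populations exist: one in which the
intron upstream of the micro exon is already spliced (W: upstream exon
joined directly to the micro exon, downstream intron still present) and one in
which the downstream intron is spliced (X: upstream intron still present,
micro exon joined to the downstream exon). Mapped to the genome, W-reads and
X-reads each retain a fragment of the annotated intron, and the two retained
fragments overlap in exactly the micro exon. The pipeline operationalises
this: the overlap of the retained-intron intervals of a paired W-like and
X-like contig is the call, and the decision rule compares counts of
junction-spanning intermediate reads against counts of pre-editing spliced
reads.

## Coordinate and annotation model

All internal coordinates are 0-based half-open on the forward strand; GFF3 I/O
converts to 1-based inclusive, and positions in human-facing reports are
1-based. mRNA order of exons comes from an explicit `exon_number` attribute,
never from genomic order, because trans-spliced exons are not collinear.
Introns are derived, not annotated: mRNA-consecutive exons on the same strand
with a positive transcription-direction gap define a cis intron; any other
neighbour pair is a trans-junction with no genomic interval. Abutting
same-strand exons are rejected (they should be merged). Circular genomes are
supported for sequence access, but annotations wrapping the origin are
rejected in this version and the generator places the gene away from the
origin; this avoids modular-interval arithmetic in every downstream
computation.

## Synthetic study conditions

The generator emulates the fragmented mitochondrial cox1 architecture. Unless
configured otherwise: nine exons totalling exactly 1,605 coding nucleotides
(the concatenated-exon length of the real gene), an 11-nt exon 4, a 1-nt exon
7 (the micro exon, base C), remaining exon lengths drawn uniformly from
[50, 400] under three constraints — the total, the requirement that the micro
exon start a codon (so `C` + the first two bases of exon 8, `AT`, form the
CAT/His codon), and a minimum length of 150 nt for the micro exon's
neighbouring exons so that intermediate transcripts comfortably exceed the
library insert. Exons are laid out in three blocks (3 exons `+`, 2 exons `-`,
4 exons `+`), giving six cis introns and two trans-junctions. Cis introns are
150–600 nt of uniform random sequence ending in G (the group-I hallmark); the
two introns flanking the micro exon are drawn at 150–300 nt each so their sum
stays in the ordinary intron range. The upstream flanking intron starts with
`T` — the base a pre-discovery annotation annexes to the upstream exon as the
putative editing site (making the naive focal codon `TAT`/Tyr) — and ends with
the `GG` of the splice motif; the downstream intron begins with `AA` and ends
with `G`. The generator redraws intron sequence until the 5-mer motif
(`GG`+`C`+`AA`) occurs exactly once within the flanking intron pair, and
verifies that the CDS it assembled from the genome equals the CDS it
constructed. The upstream exon ends in `T` (the group-I 3'-exon rule).

Transcript worlds share one genome and differ only in the population:

* `micro_exon`: one unspliced precursor per trans-spliced block (a stand-in
  for polycistronic pre-mRNA; multi-gene precursors are out of scope), the two
  intermediates, and the mature mRNA Y, weighted 2 : 1 : 1 : 4 — most reads
  come from unspliced or mature molecules, as in real libraries.
* `editing`: precursors, the spliced pre-editing transcript Z (mature sequence
  with `T` at the focal site — exactly the naive annotation's CDS), and the
  edited mature Y, weighted 2 : 1 : 4.

Intermediates are modelled as full partially spliced molecules: the unspliced
micro-exon block with exactly one flanking intron removed. The W/X forms
described above are the junction neighbourhoods of these molecules. This
matters geometrically: paired-end sequencing observes only the ends of a
~300-nt fragment, so a junction placed in the interior of a short transcript
would never be read; on the full molecule the junction is reachable by the
fragment-start mate at its natural sampling rate.

Read simulation: 76-bp unstranded pairs, insert ~ Normal(300, 30) (the insert
size is a free parameter of the library model, not a reported value), fragment
orientation uniformly random, substitution errors i.i.d. per base at 0.5% by
default, constant Q30 quality strings (the pipeline never uses qualities —
errors are injected independently of the quality string). Read pairs per
transcript are `round(weight x coverage x length / (2 x read_len))`; a
fragment whose insert exceeds the transcript after three redraws is skipped
with a warning. No indels, PCR duplicates, quality structure, or off-target
background are simulated — so passing the closed loop demonstrates the
inference logic under the stated error model, not robustness to real-library
artefacts (adapter read-through, chimeras, indel errors, expression
heterogeneity).

Every read carries ground truth: source transcript, coordinates, orientation,
and an expected splicing-stage class. The expected class is computed by
enumerating the read's ideal placements from its known source coordinates —
scored with the same placement-scoring rules as the mapper, over the diagonals
implied by the source (a diagonal is only usable when its underlying block is
at least k long, the intrinsic sensitivity limit of a k-mer seed) — and
applying the same pure classification rules as the pipeline. The closed loop
therefore tests whether seed-and-extend mapping over the whole reference
rediscovers from raw sequence what perfect knowledge of provenance implies.
Reads whose geometry supports no class, or more than one, are truth-labelled
ambiguous.

## Split-read mapping

The aligner indexes the reference with exact 15-mers and places each read
(both orientations — the data are unstranded) either as one contiguous segment
or as two same-strand segments separated by a reference gap in
[`min_intron_gap`=30, `max_intron_gap`=10000]. There are no indels within
segments, matching the substitution-only error model; real-data indels are out
of scope. Score is matches − mismatches; split placements carry no gap penalty
but each segment must be at least `min_anchor`=12 long and carry at most
`floor(0.04 x segment_length)` mismatches. Contiguous placements may soft-clip
up to 3 bases at each read end; split placements must cover the whole read.
Two segments per read is a hard design limit: 76-nt reads spanning two splice
sites are vanishingly rare, and the evidence reads here span one junction.
Reads crossing trans-spliced junctions are not split-mapped across strands;
they are recovered through the parallel mapping against the mature CDS.

Ties are broken deterministically: lowest reference coordinate of the first
segment, `+` before `-`, fewer segments, then the leftmost split point. The
leftmost-split rule also canonicalises genuinely ambiguous junctions (when the
base at the boundary matches on both sides) so that all reads spanning one
junction report identical gap coordinates. A brute-force oracle
(`map_read_bruteforce`, used only in tests) enumerates every placement without
seeding and must agree with the mapper on desk-scale instances; the seeded
mapper's only sensitivity loss relative to the oracle is segments shorter than
k, which carry no exact 15-mer seed.

## Classification

A read's label is a pure function of its maximal-score placements and the gene
model. `mature`: contiguous CDS placement crossing an exon–exon junction;
`unspliced`: contiguous genome placement covering exonic and intronic
sequence; `intermediate`: two-segment genome placement whose segments jointly
cover exonic and intronic sequence. All three categories require at least
`min_overhang`=8 bases of each evidence type: 1–3-base overhangs are within
soft-clip reach and a 1-nt micro exon must not count as exonic overhang on its
own. The margin is applied uniformly (not only to `intermediate`) because a
placement whose overhang is below it is equally undecidable for every
category. Equal-score placements in more than one category, or in none (a
read inside a single exon maps equally well to CDS and genome), give
`ambiguous`. Mates are classified independently; a pair with conflicting
classes contributes two observations.

## Assembly of intermediates

Intermediate reads are assembled anchored on their genomic alignments: reads
sharing a spliced junction (identical gap coordinates) stack into one pileup;
consensus is per-column majority with ties resolved toward the reference base
(substitution errors are rare and unbiased, so ties are overwhelmingly
error-vs-truth). Pileups are then greedily merged in descending
coordinate-overlap order when they share at least `min_overlap`=20 columns
with at most `max_overlap_mismatch`=0 consensus disagreements — but never
across *different* junction signatures: a sequencing error adjacent to a
junction can shift a single read's optimal split point by a base, and merging
that read's pileup into the clean contig would corrupt the junction evidence.
Contigs supported by fewer than `min_reads`=2 reads are dropped as noise for
the same reason. Sequence-level overlap assembly of raw reads was rejected as
the mechanism because with zero tolerated mismatches any error-bearing read
could never join a contig; anchoring on the alignment coordinates uses
information the pipeline has already paid for and makes the consensus
error-correcting.

## Calling, validation, re-annotation

Within each annotated cis intron, contigs are typed by provenance in mRNA
sense: exonic→intronic is W-like, intronic→exonic is X-like. For a W/X pair,
the intersection of their retained-intron intervals is the candidate micro
exon; empty intersections yield no call, intersections longer than
`max_micro_exon_len`=30 are rejected (logged), the first valid call per intron
wins, and one-sided evidence is reported as a half-supported candidate, never
a call — the defining evidence is two-sided. The flanking introns of a call
extend to the observed splice junctions of the two contigs, which is how the
upstream exon's annexed base is discovered: the W contig's junction starts one
base before the annotated exon end, so re-annotation truncates the exon
accordingly, splits the intron in two, inserts the new exon and renumbers
mRNA order (8 exons → 9). Applying the same call twice is an error.

Validation sets four flags: `frame_preserved` (re-annotated CDS length ≡ 0
mod 3), `conserved_codon` (code-4 translation has His at the codon containing
the micro exon — the focal site is taken from the call, never hard-coded),
`upstream_terminal_t` (the re-annotated upstream exon ends in `T` in mRNA
sense), and `motif_match` (pre-mRNA context `GG`[call]`AA`). Flags record
failures rather than raising.

## The decision

`decide_hypothesis` is a pure function of counts: micro_exon requires zero
pre-editing spliced reads and at least `min_junction`=3 intermediate reads
(configurable; chosen as a minimal-evidence floor well below the tens of
junction reads the default conditions produce); editing requires the mirror
image; everything else is inconclusive. This is a stated operational
criterion, not a statistical test; a likelihood-based comparison accounting
for coverage at the focal site is future work.

The pipeline feeds it counts from the focal site in CDS coordinates — the
called micro exon's CDS offset when a call exists, otherwise the site where
mature reads consistently disagree with the reference CDS (non-reference
fraction ≥ 0.5 at depth ≥ 5). Base observations at the site count toward a
transcript population only above a noise floor of
`max(2, 0.05 x site depth)`: phantom bases arrive at roughly error_rate/3 per
alternative base per read (≈0.2–0.3% of depth at the simulated error rates),
far below 5%, while a genuine pre-editing population in the editing world is
~20% of depth. A depth-relative floor is necessary because at 1% error and
~100x site depth an absolute floor of two reads is occasionally crossed by
noise alone.

## Motif scan and comparative statistics

Without RNA-seq, candidate sites in a related genome are found by an
annotation-constrained scan: positions inside a named cis intron whose
pre-mRNA context matches the motif and whose hypothetical call — substituting
for the terminal base the current annotation assigns to the upstream exon —
passes the frame, conserved-codon and terminal-T checks. The scan is
deliberately not genome-wide (a 5-mer is not specific at genome scale, and
the biological claim is intron-contextual), and it does not assume the motif
is unique: all validating sites are returned and the report shows
multiplicity. The cross-species report scans each locus, flags loci missing
the intron rather than failing, and adds pairwise global-alignment identity of
the host introns as context (the synthetic five-species panel shows ~50%
intron identity with the site present in all five — conservation of the motif,
not the background). Exon-identity statistics compare two equal-length
concatenated exon sets per site, annotate each substitution with its exon,
codon position and synonymy under code 4 (holding the partner codon fixed),
and refuse pairs that need gaps to align, since that means the exon models
disagree. Group-IB secondary-structure prediction is out of scope; splice-site
plausibility is checked at sequence level only.

## Numerical and reproducibility choices

Pairwise alignment is classical Needleman–Wunsch (match +1, mismatch −1, gap
−2, linear) with a deterministic traceback (diagonal > up > left); percent
identity is identical columns over alignment length. Translation uses genetic
code 4 via the standard codon table. Every stochastic component takes a
single integer seed: the locus generator consumes its config seed, the read
simulator a seed derived from it by a fixed offset, and two runs with the same
config produce byte-identical FASTQ and semantically identical reports
(timestamps live only in logs). The full default run (≈8,000 reads against a
≈4.6-kb locus plus its 1,605-nt CDS) takes about 1.5 s on one CPU; the
closed-loop property suite runs 30 generator seeds at 20x coverage and 1%
error, sizes chosen to exercise the inference across locus geometries while
keeping the whole test suite near one minute.

## Known limitations

Maximum one spliced gap per read and no cross-strand split placements; no
indel or quality-aware scoring; annotations wrapping a circular origin are
rejected; intermediate-stage chronology (which intron splices first) is not
inferable from short reads and is not modelled as ordered; the decision rule
is count-based, not probabilistic; multiple micro exons within one intron are
not called (first valid call wins, the rest are logged). The per-transcript
abundance weights are plausible defaults, not estimates. Sampling noise can
defeat the closed loop in rare seeds: with a ~300-nt insert, junction coverage
comes only from fragment-start mates, and a locus geometry that happens to
draw no junction-spanning fragment for one intermediate leaves that side of
the evidence empty (observed once in 30 seeds at 20x).
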