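# Methods

This note documents the models and procedures `lncforge` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Coordinates and containers

All internal coordinates are 0-based half-open on the forward strand;
conversion happens only at format boundaries (GTF is 1-based inclusive;
chain files carry reversed-strand target coordinates for minus-orientation
chains). A transcript is an ordered list of disjoint, non-adjacent exons on
one strand; its intron chain ((donor₁, acceptor₁), …) is derived, with the
donor at the first intronic base and the acceptor at the exclusive intron
end. Strand `.` is permitted only on evidence-track intervals, never on
transcripts, because every transcript-level analysis here is strand-aware.

## Transcript identity and merging

Transcript identity ignores termini: models group by (chromosome, strand,
intron chain). The merged representative takes the extremal termini — the
5′-most start and 3′-most end among members — so the full evidence span is
preserved, and member ids are retained as provenance. Monoexonic models have
an empty chain, so they instead deduplicate by ≥ 50% reciprocal span overlap
on the same strand, linked single-linkage through a union–find. Single
linkage is a deliberate choice: reciprocal overlap is not transitive, and
linking through intermediates matches how terminus-jittered observations of
one unspliced transcript chain together. Merging is idempotent and invariant
to input order (groups are emitted in sorted key order).

## Novelty and acceptance filtering

Novelty calls use a fixed precedence so the call is deterministic: a model is
*known* if its chain matches a reference transcript (monoexonic: ≥ 50%
reciprocal overlap with a monoexonic reference transcript); otherwise
*novel-in-gene* on ≥ 1 bp same-strand exonic overlap; otherwise *intronic*
when contained in a same-strand gene span without exonic overlap; otherwise
*antisense* on opposite-strand exonic overlap; otherwise *intergenic*.

The acceptance filter evaluates three independent predicates and records all
applicable rejection reasons per model, so filter order can never change the
accepted set:

- **antisense_pc** — ≥ 1 bp exon–exon overlap with a protein-coding gene on
  the opposite strand. Exon-level (not span-level) overlap is used because
  span overlap would also reject models lying in protein-coding introns,
  which are retained for separate analysis.
- **pseudogene_contained** — the model span lies entirely within a
  pseudogene locus span, on either strand. Containment is strand-agnostic
  because "genomic bounds" is a span-level notion and annotated pseudogene
  orientation is unreliable.
- **low_junction_support** — any intron with short-read support strictly
  below `min_junction_reads` (default 50; a count of exactly 50 passes).
  Monoexonic models pass vacuously. Absent table entries count as 0.

Models whose exons bridge ≥ 2 distinct same-strand lncRNA genes are flagged
(`merge_genes`) but stay in the accepted set: silently fusing loci is the one
error an automated pipeline must not make, so these go to manual review.

## Decoy models

A decoy copies the exon/intron length sequence and strand of a uniformly
sampled source transcript and is placed at a uniformly sampled position on
the same chromosome; placements whose span comes within `buffer` (default
1000 bp) of any annotated locus are rejected and resampled, up to
`max_attempts` (default 1000) before erroring. Decoys may overlap each
other — background placements are independent — and only integer RNG draws
are used, so a fixed seed reproduces the set bit-for-bit across platforms.
This preserves the two properties the comparisons rely on: transcript
structure statistics identical to the source set (the multiset of exon
count × exonic length is exactly preserved) and guaranteed non-genic
placement. GC content and repeat context of the sources are deliberately not
matched.

## Orthology

Gene-level projection (union of transcript exons) is used rather than
per-transcript, since ortholog counts are reported per gene. Each exon is
projected through the single best covering chain (highest score, ties by
chain id) — the liftover best-chain convention. Minus-orientation chains
convert reversed-target coordinates to forward coordinates and flip the
fragment strand. A target gene is a candidate ortholog when its exons
overlap the projected bases on the correct strand (source strand, flipped
iff the chain orientation is minus) with

- overlapped projected bp / total projected bp ≥ `min_exon_overlap_fraction`
  (default 0.5), and
- fraction of exons mapping at all ≥ `min_exons_mapped` (default 0.5).

Both defaults are this package's explicit stand-ins, exposed as parameters;
they are not published constants. An orthology edge requires strict
reciprocity (each gene among the other's candidates through its own chain
direction), which makes the edge relation symmetric by construction;
connected components of the bipartite graph are labeled 1:1, 1:many, many:1
or many:many. Note that with the 0.5 overlap threshold a 1:many call
requires the projected bases to split evenly among targets; asymmetric
splits resolve to the dominant partner.

## Evidence support

Each evidence type uses the distance its data model implies:

- **TSS vs initiation clusters** (CAGE and predicted-initiation tracks):
  nearest cluster *edge* within ± 50 bp, inclusive; a covering cluster has
  distance 0. Stranded clusters must match the TSS strand. Predicted
  initiation evidence is consumed with the same ± 50 bp contract as CAGE —
  one uniform evidence interface.
- **polyadenylation motif**: AATAAA or ATTAAA on the transcript's sense
  strand, with the motif's first base d bases upstream of the 3′-terminal
  base, 10 ≤ d ≤ 50 (bounds inclusive).
- **cCREs**: distance from the TSS to the element *center*, strictly less
  than 2 kb. Reclassification permits exactly two transitions —
  CA-H3K4me3 → PLS below 200 bp and dELS → pELS below 2 kb — conserves the
  record count and is idempotent for a fixed TSS set.
- **TF peaks**: per-TF merged peak coverage of 500 bp windows tiling
  −5 kb..+5 kb around each TSS, strand-oriented (upstream negative, so
  minus-strand profiles flip before aggregation), averaged over TSSs then
  over TFs; plus the per-TSS count of distinct TFs with a peak covering the
  TSS base itself.
- **GWAS hits**: strand-agnostic point positions; duplicated positions count
  once per record. Density = hits in the (deduplicated) region base set per
  100 kb. The meta-gene profile uses absolute 1 kb bins over ± 15 kb flanks
  and 20 meta-bins over the rescaled gene body, pooling hits and lengths
  across loci before dividing.
- **small RNAs**: hosted iff fully inside a transcript's genomic span,
  introns included, on the same strand — span-level because intron-processed
  precursors (miRNA/snoRNA hosts) are the biological case of interest.

## Conservation

Per-transcript exon score = arithmetic mean of per-base track scores over
covered exonic positions; uncovered bases are excluded from numerator and
denominator rather than imputed as 0, since score tracks legitimately have
gaps and zero-imputation would bias means toward neutral. The junction score
pools the first `site_window` intronic bases after each donor and the last
`site_window` before each acceptor; the default of 2 bp is the smallest
window containing the invariant GT/AG dinucleotides, and the statistic
depends only on the intron chain, never on termini. Classification against
the neutral band (default −1.0..+1.0) assigns boundary values to neutral
("between" read inclusively). `calibrate_band` instead takes the central
`central_mass` quantiles (default 0.95) of decoy exon means, requiring
≥ 100 scores and a non-degenerate spread.

## Synthetic data: what it emulates, what it does not

The generator emulates the *statistical structure* the analyses assume, at
desk scale (two chromosomes of 500 kb and 400 kb; 14 protein-coding, 24
lncRNA, 5 pseudogene and 11 small-RNA loci; 40 candidate intron chains
instantiated in 1–3 of 6 tissue/stage/capture samples):

- candidate classes planted disjointly at fractions 0.30 known / 0.20 novel
  in-gene / 0.175 novel intergenic / 0.10 antisense / 0.075
  pseudogene-contained / 0.15 low-support, so filter truth is unambiguous;
- junction counts are overdispersed (negative binomial, mean ≈ 200) but hard-
  clipped: planted low-support introns draw from 5–49 reads, everything else
  ≥ 50 — only the threshold crossing matters to the analyses;
- evidence tracks carry TSS-proximal enrichment (CAGE clusters jittered
  σ = 10 bp around 85% of real TSSs; promoter-like cCREs within 200 bp;
  deliberately misclassified dELS/CA-H3K4me3 records near TSSs for the
  reclassification stage; TF peaks at 0.8 probability within ± 300 bp of
  TSSs over a 5 × 10⁻⁵/bp background; GWAS hits at 10⁻⁴/bp with a 2×
  multiplier planted on the *union* of gene bodies so overlapping loci do
  not compound);
- the conservation track is zero-mean noise (σ = 0.3, 25 bp segments) with
  planted conserved transcripts at mean +3.0 over exons and 10 bp splice
  windows;
- genome B is genome A with planted deletions (lost genes), a uniform
  coordinate shift, and consistent chain files in both directions; planted
  1:2 genes have palindromic exon lengths so both halves meet the 0.5
  reciprocal-overlap threshold exactly;
- polyadenylation motifs are planted 12–48 bp upstream of a labeled 70% of
  3′ ends and scrubbed elsewhere; the recorded truth reflects the sequence
  actually generated (overlapping 3′-end windows can occasionally flip a
  label, which the truth table captures).

It does **not** emulate: realistic sequence composition (uniform random
nucleotides, no repeats or GC structure), sequence divergence between the
genomes (chains are exact), read-level noise (no FASTQ/BAM), expression
levels beyond junction counts, or overlapping/nested gene architecture
beyond small RNAs hosted in lncRNA introns. Passing tests therefore
demonstrate correctness of the *computational contracts* — grouping,
filtering, projection, window logic, classification — not robustness to
alignment artifacts or biological edge cases absent from the simulation.

## Numerical and testing choices

Brute-force oracles back the nontrivial operations: an O(n²) pairwise
grouping oracle for merging (500 models), a per-base projection oracle for
chains (including minus orientation), and a per-base accumulation oracle for
conservation means. Statistical acceptance checks state their tolerances up
front: TF-profile flatness is tested at n = 200 TSS × 5 TFs against the
analytic coverage expectation 1 − (1 − w/(L − w + 1))^N with a 3-standard-
error bound computed over the n observations (conservative, since each
observation already averages 500 bases); the planted 2× GWAS enrichment must
fall inside the 95% Poisson interval of the expected count; the uniform
GWAS profile must keep every bin within 4 Poisson standard deviations.
Problem sizes were chosen so the full test suite and the end-to-end demo
each run in seconds on one CPU.

## Known limitations

- Monoexonic merging by single-linkage reciprocal overlap can chain long
  runs of staggered unspliced models into one group.
- `tss_support` scans tracks linearly per TSS; fine at annotation scale
  here, but a genome-wide CAGE set would want the sorted-index path used by
  cCRE matching.
- The orthology 1:many semantics under the default 0.5 threshold are strict
  (see above); lowering `min_exon_overlap_fraction` relaxes this at the cost
  of more many:many components.
- Manual-curation steps of a production annotation workflow (resolving
  flagged locus merges, rescuing filtered models) are out of scope; the
  pipeline reports, it does not adjudicate.
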