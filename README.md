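# lncforge

Tools for integrating capture long-read (CLS) transcript models into a
reference gene annotation and characterizing the result against
functional-genomics evidence.

Long non-coding RNAs (lncRNAs) are lowly expressed and tissue-specific, so
reference catalogs built from short-read RNA-seq are fragmentary: models lack
correct 5′/3′ termini and exon connectivity. Targeted long-read sequencing
produces full-length candidate transcript models by the hundred thousand, but
folding them into a reference annotation requires (i) collapsing redundant
models, (ii) stringent acceptance filtering tuned for a minimal
false-positive rate, and (iii) downstream evidence that the accepted models
behave like genes rather than like transcriptional noise. `lncforge`
implements that computational pipeline as a tested, reusable library with a
CLI, for annotation engineers and computational biologists who want to run or
audit each stage at desk scale.

## What it computes

- **Intron-chain merging** — two models are the same transcript iff they
  share chromosome, strand and the ordered junction list
  ((d₁,a₁),…,(dₖ,aₖ)), ignoring terminal-exon boundaries; merged models take
  the 5′-most start and 3′-most end among members. Monoexonic models
  deduplicate by ≥ 50% reciprocal span overlap.
- **Novelty classification** against a reference, with fixed precedence:
  known ▸ novel transcript of a known gene (same-strand exonic overlap) ▸
  intronic ▸ antisense ▸ intergenic.
- **Acceptance filtering** with three independent rejection predicates:
  antisense to a protein-coding gene (opposite-strand exon–exon overlap),
  span containment within a pseudogene locus, and any intron supported by
  < 50 short reads (strictly less; monoexonic models pass vacuously).
  Models bridging ≥ 2 distinct same-strand lncRNA genes are flagged for
  manual review, never auto-rejected.
- **Decoy models** — exon/intron length sequences of real transcripts
  relocated by rejection sampling into intergenic space (≥ 1 kb from any
  locus), providing the non-genic background baseline for every comparison.
- **Reciprocal exon-synteny orthology** — gene exon unions projected through
  chain alignments (liftover semantics, minus-orientation handled); an edge
  a–b requires b among a's candidates *and* a among b's, with correct-strand
  overlap of ≥ 50% of projected bases; connected components classify pairs
  as 1:1, 1:many, many:1, many:many.
- **Evidence support** — TSS vs CAGE-like clusters (±50 bp to the nearest
  cluster edge), polyadenylation motifs (AATAAA/ATTAAA 10–50 bp upstream of
  the 3′ end, strand-aware), cCRE support (center < 2 kb) and
  TSS-proximity-dependent reclassification (CA-H3K4me3→PLS at < 200 bp,
  dELS→pELS at < 2 kb), TF peak-coverage profiles in 500 bp windows over
  ±5 kb of each TSS, GWAS hit densities per 100 kb and ±15 kb meta-gene
  profiles, and small-RNA host assignment (same-strand span containment).
- **Conservation** — per-transcript mean phyloP-style scores over exonic
  bases and splice-site windows, classified against a neutral band
  (default −1..+1, calibratable from decoy score quantiles).

A seeded generator (`lncforge.synthetic`) produces every input — genomes,
annotations, candidate models with planted violations, junction counts,
evidence tracks with planted enrichments, conservation tracks and chain
files — together with the planted ground truth, so each stage's recovery is
testable.

## Worked example

```sh
lncforge demo --seed 7 --out demo/
```

runs simulate → merge → filter → decoys → orthology → characterize →
conserve on one synthetic bundle and prints:

```
merged 53 models into 40 (unique-sample fraction 0.75)
target regions detected: 0.37
accepted 27/40 merged models
decoys: 300, violations 0
orthologs: 18/24 lncRNA genes
TSS support novel vs decoy: 0.96 vs 0.00
dELS 0.17 -> 0.11; pELS 0.08 -> 0.15
small RNAs hosted: 0.55
exon-conserved fraction novel vs decoy: 0.44 vs 0.00
```

Reading this: 53 sample-level models collapse to 40 distinct intron chains,
of which 30 are detected in a single sample (0.75). The acceptance filters
reject exactly the 13 planted violations (4 antisense, 3
pseudogene-contained, 6 with a low-support intron), leaving 27. All 300
decoys land ≥ 1 kb from annotation. Of 24 lncRNA genes, 18 have reciprocal
mouse-side orthologs (the other 6 were planted as deleted). Novel models are
CAGE/initiation-supported at 96% against a decoy background of ~0%;
re-classifying cCREs with the expanded TSS set moves distal enhancer-like
elements (dELS) to proximal (pELS); and planted-conserved transcripts
separate cleanly from the neutral decoy baseline. Per-stage tables
(`filter_report.tsv`, `orthology.tsv`, `characterization.tsv`,
`conservation.tsv`, …) and a `manifest.json` land in `demo/`.

The same stages are exposed individually (`lncforge simulate|merge|filter|
decoys|orthology|characterize|conserve|validate`) and as library functions.

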