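"""Seeded synthetic-data generator for the whole pipeline.

``simulate`` produces, from a single integer seed, every input the pipeline
consumes — two genomes, reference annotations for both, candidate transcript
models with planted filter-violation classes, a junction-support table with
planted low-support introns, TSS/cCRE/TF/GWAS/small-RNA evidence tracks with
planted TSS-proximal enrichment, a conservation track with a neutral
background and planted conserved transcripts, and consistent chain files in
both directions — together with a :class:`SimTruth` record of everything that
was planted, so each stage's recovery is checkable against ground truth.

The generator emulates the *statistical structure* the analyses assume
(planted classes, threshold-crossing junction counts, proximity enrichments,
a neutral conservation baseline), not real genomes: sequences are uniform
random nucleotides apart from planted polyadenylation motifs, and the second
genome is the first one with planted deletions and a coordinate shift rather
than a diverged sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as lio
from .core import (
    Annotation,
    ChainAlignment,
    GeneLocus,
    GenomeSequence,
    GenomicInterval,
    JunctionSupportTable,
    ScoredTrack,
    SpliceJunction,
    TranscriptModel,
    ValidationError,
)

CANDIDATE_CLASSES = (
    "known",
    "novel_transcript",
    "novel_intergenic",
    "antisense_pc",
    "pseudogene_contained",
    "low_support",
)

SAMPLE_PANEL = [
    ("brain_adult_post", "brain", "adult", "post"),
    ("brain_embryo_post", "brain", "embryo", "post"),
    ("liver_adult_post", "liver", "adult", "post"),
    ("liver_embryo_post", "liver", "embryo", "post"),
    ("heart_adult_pre", "heart", "adult", "pre"),
    ("heart_adult_post", "heart", "adult", "post"),
]

TARGET_CATALOGS = ("lncbook", "noncode", "fantom_cat", "enhancers", "phylocsf")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G on byte values


@dataclass
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults are desk-scale stand-ins for the real study's inputs: candidate
    class fractions give disjoint planted filter violations; the junction
    threshold structure (< 50 vs >= 50 reads) is unambiguous; evidence
    enrichments are strong enough that real sets separate cleanly from decoy
    background; the planted target-detection rate is 0.37 and the planted
    single-sample rate 0.8, mirroring the regimes the analyses report on.
    """

    seed: int = 0
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 500_000, "chr2": 400_000}
    )
    gene_zone_fraction: float = 0.6  # genes live in the first part of each chrom
    n_protein_coding: int = 14
    n_lncrna: int = 24
    n_pseudogene: int = 5
    n_smallrna_hosted: int = 6
    n_smallrna_orphan: int = 5
    # candidate models
    n_candidates: int = 40
    class_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "known": 0.30,
            "novel_transcript": 0.20,
            "novel_intergenic": 0.175,
            "antisense_pc": 0.10,
            "pseudogene_contained": 0.075,
            "low_support": 0.15,
        }
    )
    unique_sample_fraction: float = 0.8
    # junction support counts (overdispersed; threshold structure is what matters)
    junction_mean: float = 150.0
    junction_min_supported: int = 50
    low_support_range: Tuple[int, int] = (5, 49)
    # evidence tracks
    cage_fraction: float = 0.85
    cage_jitter_sd: float = 10.0
    procapnet_fraction: float = 0.5
    background_cage_per_100kb: float = 4.0
    ccre_pls_prob: float = 0.7
    ccre_pels_prob: float = 0.5
    ccre_dels_near_prob: float = 0.35  # planted misclassified dELS (to become pELS)
    ccre_cah3k4_near_prob: float = 0.25  # planted misclassified CA-H3K4me3 (to PLS)
    ccre_background_per_class: int = 25
    n_tfs: int = 6
    tf_peak_width: int = 200
    tf_background_rate: float = 5e-5  # peaks per bp
    tf_tss_peak_prob: float = 0.8
    gwas_rate: float = 1e-4  # hits per bp, genome-wide background
    gwas_body_multiplier: float = 2.0
    # conservation
    conservation_sd: float = 0.3
    conservation_seg_len: int = 25
    conserved_fraction: float = 0.3
    conserved_mean: float = 3.0
    junction_site_plant: int = 10
    # polyA
    polya_fraction: float = 0.7
    polya_near: int = 10
    polya_far: int = 50
    # orthology fates of lncRNA genes
    ortholog_one_to_one: float = 0.6
    ortholog_one_to_two: float = 0.15  # remainder is lost
    b_shift: int = 4000
    b_extra: int = 12_000
    # targets
    target_detected_fraction: float = 0.37

    def __post_init__(self) -> None:
        if sum(self.class_fractions.values()) > 1 + 1e-9:
            raise ValidationError("candidate class fractions must sum to <= 1")
        if self.ortholog_one_to_one + self.ortholog_one_to_two > 1 + 1e-9:
            raise ValidationError("ortholog fate fractions must sum to <= 1")
        if not self.low_support_range[1] < self.junction_min_supported:
            raise ValidationError("planted low-support counts must sit below threshold")


@dataclass
class SimTruth:
    """Ground truth for everything the generator planted."""

    model_class: Dict[str, str] = field(default_factory=dict)  # instance id -> class
    chain_class: Dict[str, str] = field(default_factory=dict)  # chain id -> class
    chain_samples: Dict[str, List[str]] = field(default_factory=dict)
    ortholog_map: Dict[str, List[str]] = field(default_factory=dict)  # A gene -> B genes
    conservation_label: Dict[str, str] = field(default_factory=dict)
    polya: Dict[str, bool] = field(default_factory=dict)
    low_support_junctions: Set[SpliceJunction] = field(default_factory=set)
    hosted_smallrnas: Dict[str, bool] = field(default_factory=dict)
    target_detected: Dict[str, bool] = field(default_factory=dict)
    params: Dict[str, float] = field(default_factory=dict)


@dataclass
class SimBundle:
    config: SimConfig
    genome_a: GenomeSequence
    genome_b: GenomeSequence
    reference_a: Annotation
    reference_b: Annotation
    candidates: List[TranscriptModel]
    samples: pd.DataFrame
    junctions: JunctionSupportTable
    cage: ScoredTrack
    procapnet: ScoredTrack
    ccres: ScoredTrack
    tf_peaks: Dict[str, ScoredTrack]
    gwas: ScoredTrack
    smallrna: ScoredTrack
    targets: ScoredTrack
    conservation: ScoredTrack
    chains_ab: List[ChainAlignment]
    chains_ba: List[ChainAlignment]
    truth: SimTruth

    @property
    def chrom_sizes_a(self) -> Dict[str, int]:
        return dict(self.config.chrom_sizes)

    @property
    def chrom_sizes_b(self) -> Dict[str, int]:
        return {c: s + self.config.b_extra for c, s in self.config.chrom_sizes.items()}

    def candidate_annotation(self) -> Annotation:
        return Annotation.from_transcripts(self.candidates)

    def lncrna_reference(self, which: str = "a") -> Annotation:
        ref = self.reference_a if which == "a" else self.reference_b
        return subset_by_biotype(ref, "lncRNA")

    def write(self, out_dir) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tf_peaks").mkdir(exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        paths: Dict[str, Path] = {}

        def _p(key: str, rel: str) -> Path:
            paths[key] = out / rel
            return paths[key]

        lio.write_fasta(self.genome_a, _p("genome_a", "genome_a.fa"))
        lio.write_fasta(self.genome_b, _p("genome_b", "genome_b.fa"))
        lio.write_chrom_sizes(self.chrom_sizes_a, _p("sizes_a", "genome_a.sizes.tsv"))
        lio.write_chrom_sizes(self.chrom_sizes_b, _p("sizes_b", "genome_b.sizes.tsv"))
        lio.write_gtf(self.reference_a, _p("reference_a", "reference_a.gtf"))
        lio.write_gtf(self.reference_b, _p("reference_b", "reference_b.gtf"))
        lio.write_gtf(
            Annotation.from_transcripts(self.candidates),
            _p("candidates", "candidates.gtf"),
        )
        self.samples.to_csv(_p("samples", "samples.tsv"), sep="\t")
        lio.write_junction_support(self.junctions, _p("junctions", "junctions.tsv"))
        lio.write_track(self.cage, _p("cage", "cage.bed"))
        lio.write_track(self.procapnet, _p("procapnet", "procapnet.bed"))
        lio.write_track(self.ccres, _p("ccres", "ccres.bed"))
        for tf, track in sorted(self.tf_peaks.items()):
            lio.write_track(track, _p(f"tf_{tf}", f"tf_peaks/{tf}.bed"))
        lio.write_track(self.gwas, _p("gwas", "gwas.bed"))
        lio.write_track(self.smallrna, _p("smallrna", "smallrna.bed"))
        lio.write_track(self.targets, _p("targets", "targets.bed"))
        lio.write_track(
            self.conservation, _p("conservation", "conservation.bedgraph"), "bedgraph"
        )
        lio.write_chain(self.chains_ab, _p("chain_ab", "a_to_b.chain"))
        lio.write_chain(self.chains_ba, _p("chain_ba", "b_to_a.chain"))

        t = self.truth
        pd.DataFrame(
            sorted(t.model_class.items()), columns=["model_id", "class"]
        ).to_csv(_p("truth_models", "truth/model_class.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [(a, ",".join(bs)) for a, bs in sorted(t.ortholog_map.items())],
            columns=["gene_a", "genes_b"],
        ).to_csv(_p("truth_orthologs", "truth/orthologs.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(t.conservation_label.items()), columns=["transcript_id", "label"]
        ).to_csv(_p("truth_conservation", "truth/conservation.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(t.polya.items()), columns=["transcript_id", "polya"]
        ).to_csv(_p("truth_polya", "truth/polya.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted((j.chrom, j.strand, j.donor, j.acceptor) for j in t.low_support_junctions),
            columns=["chrom", "strand", "donor", "acceptor"],
        ).to_csv(_p("truth_lowjx", "truth/low_support_junctions.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(t.hosted_smallrnas.items()), columns=["small_rna", "hosted"]
        ).to_csv(_p("truth_smallrna", "truth/smallrna_hosted.tsv"), sep="\t", index=False)
        return paths


def subset_by_biotype(annotation: Annotation, biotype: str) -> Annotation:
    return Annotation([g for g in annotation if g.biotype == biotype])


# --------------------------------------------------------------------------
# internals
# --------------------------------------------------------------------------

class _Placer:
    """Sequential left-to-right locus placement with random gaps."""

    def __init__(self, rng, zones: Dict[str, Tuple[int, int]], gap: Tuple[int, int]):
        self.rng = rng
        self.cursor = {c: z[0] for c, z in zones.items()}
        self.limits = {c: z[1] for c, z in zones.items()}
        self.order = sorted(zones)
        self.gap = gap
        self._next = 0

    def place(self, length: int, chrom: Optional[str] = None) -> Tuple[str, int]:
        tries = 0
        while tries <= len(self.order):
            if chrom is None:
                c = self.order[self._next % len(self.order)]
                self._next += 1
            else:
                c = chrom
            gap = int(self.rng.integers(self.gap[0], self.gap[1]))
            start = self.cursor[c] + gap
            if start + length <= self.limits[c]:
                self.cursor[c] = start + length
                return c, start
            if chrom is not None:
                break
            tries += 1
        raise ValidationError(
            f"infeasible packing: no room for a {length} bp locus"
            + (f" on {chrom}" if chrom else "")
        )


def _sample_structure(
    rng,
    n_exons: Optional[int] = None,
    palindromic: bool = False,
    exon_loc: float = math.log(150.0),
    exon_spread: float = 0.4,
    intron_loc: float = math.log(700.0),
    intron_spread: float = 0.5,
) -> List[Tuple[int, int]]:
    """Exon (start, end) offsets from 0, log-normal lengths."""
    if n_exons is None:
        n_exons = 2 + int(rng.poisson(2.0))
    def _len(loc, spread, lo, hi):
        return int(min(max(rng.lognormal(loc, spread), lo), hi))
    exon_lens = [_len(exon_loc, exon_spread, 60, 600) for _ in range(n_exons)]
    if palindromic:
        half = exon_lens[: n_exons // 2]
        exon_lens = half + half[::-1]
        if n_exons % 2:  # force even count for clean half-splits
            exon_lens = half + half[::-1]
    intron_lens = [
        _len(intron_loc, intron_spread, 250, 2500) for _ in range(len(exon_lens) - 1)
    ]
    exons = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    return exons


def _shift_exons(exons: Sequence[Tuple[int, int]], offset: int) -> Tuple[Tuple[int, int], ...]:
    return tuple((s + offset, e + offset) for s, e in exons)


def _jitter_termini(rng, exons: Tuple[Tuple[int, int], ...], amount: int = 100):
    exons = list(exons)
    fs, fe = exons[0]
    ls, le = exons[-1]
    max_shrink_f = max(0, (fe - fs) - 30)
    d1 = int(rng.integers(-amount, min(amount, max_shrink_f) + 1))
    exons[0] = (max(0, fs + d1), fe)
    if len(exons) == 1:
        s, e = exons[0]
        max_shrink_l = max(0, (e - s) - 30)
        d2 = int(rng.integers(-min(amount, max_shrink_l), amount + 1))
        exons[0] = (exons[0][0], e + d2)
    else:
        max_shrink_l = max(0, (le - ls) - 30)
        d2 = int(rng.integers(-min(amount, max_shrink_l), amount + 1))
        exons[-1] = (ls, le + d2)
    return tuple(exons)


def _real_tss_list(ref_a: Annotation, candidates: Sequence[TranscriptModel]):
    out = []
    for g in ref_a:
        if g.biotype in ("protein_coding", "lncRNA"):
            for t in g.transcripts:
                out.append((t.chrom, t.tss, t.strand))
    for m in candidates:
        out.append((m.chrom, m.tss, m.strand))
    # unique, stable order
    return sorted(set(out))


def simulate(config: SimConfig) -> SimBundle:
    rng = np.random.default_rng(config.seed)
    sizes = dict(config.chrom_sizes)
    zones = {
        c: (5000, int(s * config.gene_zone_fraction)) for c, s in sizes.items()
    }
    placer = _Placer(rng, zones, gap=(1500, 4000))
    truth = SimTruth(params={
        "tf_background_rate": config.tf_background_rate,
        "gwas_rate": config.gwas_rate,
        "gwas_body_multiplier": config.gwas_body_multiplier,
        "conservation_sd": config.conservation_sd,
        "conserved_mean": config.conserved_mean,
    })

    # ---- orthology fates for lncRNA genes (decided before structures) ----
    n_lnc = config.n_lncrna
    n_121 = int(round(config.ortholog_one_to_one * n_lnc))
    n_122 = int(round(config.ortholog_one_to_two * n_lnc))
    fates = (["one_to_one"] * n_121 + ["one_to_two"] * n_122
             + ["lost"] * (n_lnc - n_121 - n_122))
    fates = [fates[i] for i in rng.permutation(n_lnc)]

    # ---- reference annotation A ----
    ref_genes: List[GeneLocus] = []

    def _add_gene(gid, biotype, exons_rel, length=None, chrom=None):
        span = exons_rel[-1][1]
        c, start = placer.place(span, chrom)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        t = TranscriptModel(
            id=f"{gid}.t1", chrom=c, strand=strand,
            exons=_shift_exons(exons_rel, start), gene_id=gid, biotype=biotype,
        )
        g = GeneLocus(gid, biotype, c, strand, [t])
        ref_genes.append(g)
        return g

    pc_genes = [
        _add_gene(f"PCG{i+1:03d}", "protein_coding",
                  _sample_structure(rng, n_exons=4 + int(rng.poisson(2.0))))
        for i in range(config.n_protein_coding)
    ]
    lnc_genes = []
    for i in range(n_lnc):
        if fates[i] == "one_to_two":
            exons = _sample_structure(rng, n_exons=4, palindromic=True)
        else:
            exons = _sample_structure(rng, n_exons=max(3, 2 + int(rng.poisson(2.0))))
        lnc_genes.append(_add_gene(f"LNC{i+1:03d}", "lncRNA", exons))
    pseudo_genes = [
        _add_gene(f"PSG{i+1:03d}", "pseudogene",
                  [(0, int(rng.integers(2500, 5000)))])
        for i in range(config.n_pseudogene)
    ]

    # hosted small RNAs inside lncRNA introns (same strand), orphans intergenic
    smallrna_ivs: List[GenomicInterval] = []
    host_pool = [
        g for g in lnc_genes
        if any(a - d >= 500 for d, a in g.transcripts[0].introns)
    ]
    for i in range(config.n_smallrna_hosted):
        g = host_pool[i % len(host_pool)]
        introns = [x for x in g.transcripts[0].introns if x[1] - x[0] >= 500]
        d, a = introns[int(rng.integers(0, len(introns)))]
        length = int(rng.integers(80, 150))
        start = int(rng.integers(d + 50, a - 50 - length))
        name = f"mir_hosted_{i+1:02d}"
        smallrna_ivs.append(GenomicInterval(g.chrom, start, start + length, g.strand, label=name))
        truth.hosted_smallrnas[name] = True
        ref_genes.append(GeneLocus(
            f"SRG_H{i+1:02d}", "small_rna", g.chrom, g.strand,
            [TranscriptModel(f"SRG_H{i+1:02d}.t1", g.chrom, g.strand,
                             ((start, start + length),),
                             gene_id=f"SRG_H{i+1:02d}", biotype="small_rna")]))
    for i in range(config.n_smallrna_orphan):
        length = int(rng.integers(80, 150))
        c, start = placer.place(length)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        name = f"mir_orphan_{i+1:02d}"
        smallrna_ivs.append(GenomicInterval(c, start, start + length, strand, label=name))
        truth.hosted_smallrnas[name] = False
    smallrna_track = ScoredTrack("smallrna", smallrna_ivs)

    ref_a = Annotation(ref_genes)

    # ---- candidate transcript models with planted classes ----
    counts = {
        cls: int(round(config.class_fractions.get(cls, 0.0) * config.n_candidates))
        for cls in CANDIDATE_CLASSES
    }
    counts["novel_intergenic"] += config.n_candidates - sum(counts.values())

    chain_defs: List[Tuple[str, str, str, Tuple[Tuple[int, int], ...]]] = []
    # (chain_id, class, chrom+strand packed separately)
    lnc_cycle = list(rng.permutation(len(lnc_genes)))
    lnc_i = 0

    def _next_lnc(min_exons=2):
        nonlocal lnc_i
        for _ in range(len(lnc_cycle)):
            g = lnc_genes[lnc_cycle[lnc_i % len(lnc_cycle)]]
            lnc_i += 1
            if len(g.transcripts[0].exons) >= min_exons:
                return g
        raise ValidationError("no lncRNA gene with enough exons")

    k = 0
    for cls in CANDIDATE_CLASSES:
        for _ in range(counts[cls]):
            k += 1
            cid = f"cand_{cls}_{k:03d}"
            if cls == "known":
                g = _next_lnc(2)
                t = g.transcripts[0]
                chain_defs.append((cid, cls, t.chrom, t.strand, t.exons))
            elif cls == "novel_transcript":
                g = _next_lnc(3)
                t = g.transcripts[0]
                skip = 1 + int(rng.integers(0, len(t.exons) - 2))
                exons = t.exons[:skip] + t.exons[skip + 1:]
                chain_defs.append((cid, cls, t.chrom, t.strand, exons))
            elif cls in ("novel_intergenic", "low_support"):
                rel = _sample_structure(rng, n_exons=2 + int(rng.poisson(1.5)))
                c, start = placer.place(rel[-1][1])
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                chain_defs.append((cid, cls, c, strand, _shift_exons(rel, start)))
            elif cls == "antisense_pc":
                g = pc_genes[int(rng.integers(0, len(pc_genes)))]
                t = g.transcripts[0]
                ex = t.exons[int(rng.integers(0, len(t.exons)))]
                # two-exon model, first exon straddling the protein-coding exon
                e1 = (max(0, ex[0] - 50), ex[1] + 50)
                e2 = (e1[1] + 400, e1[1] + 400 + 200)
                strand = "-" if t.strand == "+" else "+"
                chain_defs.append((cid, cls, t.chrom, strand, (e1, e2)))
            elif cls == "pseudogene_contained":
                g = pseudo_genes[int(rng.integers(0, len(pseudo_genes)))]
                s, e = g.start, g.end
                # keep a 150 bp margin so termini jitter (<= 100 bp) cannot
                # push an instance outside the pseudogene bounds
                start = int(rng.integers(s + 150, s + 400))
                end = int(rng.integers(e - 400, e - 150))
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                chain_defs.append((cid, cls, g.chrom, strand, ((start, end),)))
            truth.chain_class[cid] = cls

    # instantiate chains in samples
    sample_ids = [s[0] for s in SAMPLE_PANEL]
    samples = pd.DataFrame(
        [
            {"tissue": t, "stage": st, "capture": cap}
            for (_, t, st, cap) in SAMPLE_PANEL
        ],
        index=pd.Index(sample_ids, name="sample_id"),
    )
    candidates: List[TranscriptModel] = []
    for cid, cls, chrom, strand, exons in chain_defs:
        if rng.random() < config.unique_sample_fraction:
            n_samples = 1
        else:
            n_samples = int(rng.integers(2, 4))
        chosen = [sample_ids[i] for i in rng.choice(len(sample_ids), n_samples, replace=False)]
        truth.chain_samples[cid] = sorted(chosen)
        for j, sid in enumerate(sorted(chosen), 1):
            inst_exons = exons if j == 1 else _jitter_termini(rng, exons)
            iid = f"{cid}.{j}"
            candidates.append(
                TranscriptModel(
                    id=iid, chrom=chrom, strand=strand, exons=inst_exons,
                    gene_id=cid, biotype="lncRNA", tags={"sample": sid},
                )
            )
            truth.model_class[iid] = cls

    # ---- junction support table ----
    junctions = JunctionSupportTable()
    low_chains = {cid for cid, cls in truth.chain_class.items() if cls == "low_support"}
    low_junction_of: Dict[str, SpliceJunction] = {}
    for m in candidates:
        if m.gene_id in low_chains and m.gene_id not in low_junction_of and m.is_spliced:
            jx = m.junctions[0]
            low_junction_of[m.gene_id] = jx
            truth.low_support_junctions.add(jx)
    all_junctions: Set[SpliceJunction] = set()
    for t in ref_a.transcripts():
        all_junctions.update(t.junctions)
    for m in candidates:
        all_junctions.update(m.junctions)
    for jx in sorted(all_junctions, key=lambda j: (j.chrom, j.donor, j.acceptor, j.strand)):
        if jx in truth.low_support_junctions:
            lo, hi = config.low_support_range
            junctions.set(jx, int(rng.integers(lo, hi + 1)))
        else:
            extra = int(rng.negative_binomial(2, 2.0 / (2.0 + config.junction_mean)))
            junctions.set(jx, config.junction_min_supported + extra)

    # ---- genome B and chains ----
    deletions: Dict[str, List[Tuple[int, int]]] = {c: [] for c in sizes}
    lost = [g for g, f in zip(lnc_genes, fates) if f == "lost"]
    for g in lost:
        deletions[g.chrom].append((max(0, g.start - 200), g.end + 200))
        truth.ortholog_map[g.id] = []
    for c in deletions:
        deletions[c].sort()

    def _a2b_map(chrom: str):
        """Returns a2b(pos) over non-deleted positions."""
        dels = deletions[chrom]
        def a2b(pos: int) -> int:
            cum = 0
            for s, e in dels:
                if pos >= e:
                    cum += e - s
                elif pos >= s:
                    raise ValidationError("position deleted in genome B")
            return pos - cum + config.b_shift
        return a2b

    chains_ab: List[ChainAlignment] = []
    chains_ba: List[ChainAlignment] = []
    sizes_b = {c: s + config.b_extra for c, s in sizes.items()}
    for c in sorted(sizes):
        a2b = _a2b_map(c)
        blocks = []
        prev = 0
        for s, e in deletions[c] + [(sizes[c], sizes[c])]:
            if s > prev:
                blocks.append((prev, a2b(prev), s - prev))
            prev = max(prev, e)
        total = sum(b[2] for b in blocks)
        chains_ab.append(ChainAlignment(c, sizes[c], c, sizes_b[c], "+", blocks,
                                        chain_id=f"ab_{c}", score=float(total)))
        inv = [(t, s, ln) for (s, t, ln) in blocks]
        chains_ba.append(ChainAlignment(c, sizes_b[c], c, sizes[c], "+", inv,
                                        chain_id=f"ba_{c}", score=float(total)))

    ref_b_genes: List[GeneLocus] = []

    def _map_exons(g: GeneLocus) -> List[Tuple[int, int]]:
        a2b = _a2b_map(g.chrom)
        return [(a2b(s), a2b(e - 1) + 1) for s, e in g.transcripts[0].exons]

    for g in pc_genes:
        mapped = _map_exons(g)
        bid = f"B_{g.id}"
        ref_b_genes.append(GeneLocus(bid, "protein_coding", g.chrom, g.strand, [
            TranscriptModel(f"{bid}.t1", g.chrom, g.strand, tuple(mapped),
                            gene_id=bid, biotype="protein_coding")]))
    for g, fate in zip(lnc_genes, fates):
        if fate == "lost":
            continue
        mapped = _map_exons(g)
        if fate == "one_to_one":
            bid = f"B_{g.id}"
            ref_b_genes.append(GeneLocus(bid, "lncRNA", g.chrom, g.strand, [
                TranscriptModel(f"{bid}.t1", g.chrom, g.strand, tuple(mapped),
                                gene_id=bid, biotype="lncRNA")]))
            truth.ortholog_map[g.id] = [bid]
        else:  # one_to_two: split the (palindromic, even) exon list in half
            mid = len(mapped) // 2
            bids = []
            for half_i, half in enumerate((mapped[:mid], mapped[mid:]), 1):
                bid = f"B_{g.id}_h{half_i}"
                bids.append(bid)
                ref_b_genes.append(GeneLocus(bid, "lncRNA", g.chrom, g.strand, [
                    TranscriptModel(f"{bid}.t1", g.chrom, g.strand, tuple(half),
                                    gene_id=bid, biotype="lncRNA")]))
            truth.ortholog_map[g.id] = bids
    ref_b = Annotation(ref_b_genes)

    # ---- genomes (uniform random; polyA motifs handled below) ----
    genome_arrays = {
        c: _BASES[rng.integers(0, 4, size=sizes[c])].copy() for c in sorted(sizes)
    }
    genome_b_arrays = {
        c: _BASES[rng.integers(0, 4, size=sizes_b[c])].copy() for c in sorted(sizes_b)
    }

    # polyA motif planting / scrubbing on genome A
    scorable = list(ref_a.transcripts()) + candidates
    polya_plan: Dict[str, bool] = {}
    for t in sorted(scorable, key=lambda t: t.id):
        polya_plan[t.id] = bool(rng.random() < config.polya_fraction)
    _apply_polya(rng, genome_arrays, scorable, polya_plan, config)
    genome_a = GenomeSequence({c: a.tobytes().decode() for c, a in genome_arrays.items()})
    genome_b = GenomeSequence({c: a.tobytes().decode() for c, a in genome_b_arrays.items()})
    # record realized labels (collisions between nearby 3' ends may flip a few)
    from .characterization import transcript_has_polya
    for t in sorted(scorable, key=lambda t: t.id):
        truth.polya[t.id] = transcript_has_polya(
            t, genome_a, near=config.polya_near, far=config.polya_far
        )

    # ---- evidence tracks ----
    tss_list = _real_tss_list(ref_a, candidates)
    cage = ScoredTrack("cage")
    procapnet = ScoredTrack("procapnet")
    for chrom, pos, strand in tss_list:
        if rng.random() < config.cage_fraction:
            jitter = int(np.clip(round(rng.normal(0, config.cage_jitter_sd)), -40, 40))
            width = int(rng.integers(10, 31))
            center = max(width, pos + jitter)
            cage.add(GenomicInterval(chrom, center - width // 2,
                                     center - width // 2 + width, strand))
        if rng.random() < config.procapnet_fraction:
            procapnet.add(GenomicInterval(chrom, max(0, pos - 2), pos + 3, strand))
    for c in sorted(sizes):
        n_bg = int(round(config.background_cage_per_100kb * sizes[c] / 1e5))
        for _ in range(n_bg):
            p = int(rng.integers(1000, sizes[c] - 1000))
            w = int(rng.integers(10, 31))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            cage.add(GenomicInterval(c, p, p + w, strand))

    ccres = ScoredTrack("ccres")

    def _add_ccre(chrom, center, label, width=300):
        s = max(0, center - width // 2)
        ccres.add(GenomicInterval(chrom, s, s + width, ".", label=label))

    for chrom, pos, strand in tss_list:
        if rng.random() < config.ccre_pls_prob:
            _add_ccre(chrom, pos + int(rng.integers(-150, 151)), "PLS")
        if rng.random() < config.ccre_pels_prob:
            off = int(rng.integers(300, 1800)) * (1 if rng.integers(0, 2) else -1)
            _add_ccre(chrom, pos + off, "pELS")
        if rng.random() < config.ccre_dels_near_prob:
            off = int(rng.integers(300, 1900)) * (1 if rng.integers(0, 2) else -1)
            _add_ccre(chrom, pos + off, "dELS")  # misclassified: closer than 2 kb
        if rng.random() < config.ccre_cah3k4_near_prob:
            _add_ccre(chrom, pos + int(rng.integers(-150, 151)), "CA-H3K4me3")
    for c in sorted(sizes):
        for label in ("dELS", "CA-CTCF", "CA-TF", "CA", "TF", "CA-H3K4me3"):
            for _ in range(config.ccre_background_per_class):
                _add_ccre(c, int(rng.integers(1000, sizes[c] - 1000)), label)

    tf_peaks: Dict[str, ScoredTrack] = {}
    w = config.tf_peak_width
    for i in range(config.n_tfs):
        name = f"TF{i+1:02d}"
        track = ScoredTrack(name)
        for c in sorted(sizes):
            n_bg = rng.poisson(config.tf_background_rate * sizes[c])
            for p in sorted(int(x) for x in rng.integers(0, sizes[c] - w, size=n_bg)):
                track.add(GenomicInterval(c, p, p + w))
        for chrom, pos, strand in tss_list:
            if rng.random() < config.tf_tss_peak_prob:
                center = pos + int(rng.integers(-300, 301))
                s = max(0, center - w // 2)
                track.add(GenomicInterval(chrom, s, s + w))
        tf_peaks[name] = track

    gwas = ScoredTrack("gwas")
    for c in sorted(sizes):
        n_bg = rng.poisson(config.gwas_rate * sizes[c])
        for p in sorted(int(x) for x in rng.integers(0, sizes[c], size=n_bg)):
            gwas.add(GenomicInterval(c, p, p + 1))
    # plant the gene-body enrichment on the *union* of body spans so bases
    # shared by overlapping loci get exactly multiplier x background rate
    extra_rate = (config.gwas_body_multiplier - 1.0) * config.gwas_rate
    from .core import merge_intervals as _merge
    body_by_chrom: Dict[str, List[Tuple[int, int]]] = {c: [] for c in sizes}
    for g in ref_a:
        body_by_chrom[g.chrom].append((g.start, g.end))
    for m in candidates:
        body_by_chrom[m.chrom].append((m.start, m.end))
    for chrom in sorted(body_by_chrom):
        for s, e in _merge(body_by_chrom[chrom]):
            n_extra = rng.poisson(extra_rate * (e - s))
            for p in sorted(int(x) for x in rng.integers(s, e, size=n_extra)):
                gwas.add(GenomicInterval(chrom, p, p + 1))

    # ---- targets ----
    targets = ScoredTrack("targets")
    det_spans = []
    for cid, cls, chrom, strand, exons in chain_defs:
        det_spans.append((chrom, max(0, exons[0][0] - 200), exons[-1][1] + 200, cid))
    n_det = len(det_spans)
    n_total = int(round(n_det / config.target_detected_fraction))
    tail_zones = {
        c: (int(sizes[c] * config.gene_zone_fraction) + 3000, sizes[c] - 2000)
        for c in sizes
    }
    tail_placer = _Placer(rng, tail_zones, gap=(200, 800))
    cat_i = 0
    for chrom, s, e, cid in det_spans:
        label = TARGET_CATALOGS[cat_i % len(TARGET_CATALOGS)]
        cat_i += 1
        targets.add(GenomicInterval(chrom, s, e, ".", label=label))
        truth.target_detected[f"{chrom}:{s}-{e}"] = True
    for _ in range(n_total - n_det):
        length = int(rng.integers(500, 1500))
        c, start = tail_placer.place(length)
        label = TARGET_CATALOGS[cat_i % len(TARGET_CATALOGS)]
        cat_i += 1
        targets.add(GenomicInterval(c, start, start + length, ".", label=label))
        truth.target_detected[f"{c}:{start}-{start + length}"] = False

    # ---- conservation track ----
    conserved_pool = sorted(
        [t.id for t in ref_a.transcripts()
         if t.biotype in ("lncRNA", "protein_coding")]
        + sorted({m.gene_id for m in candidates})
    )
    n_cons = int(round(config.conserved_fraction * len(conserved_pool)))
    chosen = set(
        conserved_pool[i]
        for i in rng.choice(len(conserved_pool), n_cons, replace=False)
    )
    cons_exons: Dict[str, List[Tuple[int, int]]] = {c: [] for c in sizes}
    by_chain: Dict[str, List[TranscriptModel]] = {}
    for m in candidates:
        by_chain.setdefault(m.gene_id, []).append(m)
    for t in scorable:
        label = "neutral"
        key = t.gene_id if t.gene_id in by_chain else t.id
        if key in chosen:
            label = "conserved"
        truth.conservation_label[t.id] = label
    for key in sorted(chosen):
        if key in by_chain:
            members = by_chain[key]
            chrom = members[0].chrom
            exon_union = _merge([e for m in members for e in m.exons])
            jx = members[0].introns
        else:
            t = next(t for t in ref_a.transcripts() if t.id == key)
            chrom = t.chrom
            exon_union = list(t.exons)
            jx = t.introns
        for s, e in exon_union:
            cons_exons[chrom].append((max(0, s - 20), e + 20))
        sw = config.junction_site_plant
        for d, a in jx:
            cons_exons[chrom].append((d, min(d + sw, a)))
            cons_exons[chrom].append((max(a - sw, d), a))

    conservation = ScoredTrack("conservation")
    seg = config.conservation_seg_len
    for c in sorted(sizes):
        size = sizes[c]
        n_seg = (size + seg - 1) // seg
        values = np.repeat(
            np.round(rng.normal(0.0, config.conservation_sd, n_seg), 4), seg
        )[:size]
        for s, e in cons_exons[c]:
            e = min(e, size)
            values[s:e] = np.round(
                rng.normal(config.conserved_mean, config.conservation_sd, e - s), 4
            )
        # run-length encode
        change = np.flatnonzero(np.diff(values)) + 1
        bounds = np.concatenate([[0], change, [size]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            conservation.add(
                GenomicInterval(c, int(s), int(e), score=float(values[s]))
            )

    return SimBundle(
        config=config,
        genome_a=genome_a,
        genome_b=genome_b,
        reference_a=ref_a,
        reference_b=ref_b,
        candidates=candidates,
        samples=samples,
        junctions=junctions,
        cage=cage,
        procapnet=procapnet,
        ccres=ccres,
        tf_peaks=tf_peaks,
        gwas=gwas,
        smallrna=smallrna_track,
        targets=targets,
        conservation=conservation,
        chains_ab=chains_ab,
        chains_ba=chains_ba,
        truth=truth,
    )


def _apply_polya(rng, genome_arrays, transcripts, plan: Dict[str, bool], config: SimConfig):
    """Scrub polyA motifs from unlabeled 3'-end windows, then plant motifs for
    labeled transcripts at a random offset in [near+2, far-2]."""
    from .characterization import POLYA_MOTIFS

    motifs = [m.encode() for m in POLYA_MOTIFS]

    def _sense_window(t):
        far = config.polya_far
        arr = genome_arrays[t.chrom]
        if t.strand == "+":
            lo = max(0, t.end - (far + 1))
            return lo, arr[lo:t.end].tobytes(), "+"
        hi = min(len(arr), t.start + far + 1)
        sub = arr[t.start:hi].tobytes()
        rc = bytes(_COMP[b] for b in reversed(sub))
        return t.start, rc, "-"

    def _scrub(t):
        changed = True
        while changed:
            changed = False
            lo, win, strand = _sense_window(t)
            L = len(win)
            for m in motifs:
                i = win.find(m)
                while i >= 0:
                    # break the motif at its third base
                    if strand == "+":
                        genome_arrays[t.chrom][lo + i + 2] = ord("C")
                    else:
                        genome_arrays[t.chrom][lo + (L - 1) - (i + 2)] = ord("G")
                    changed = True
                    lo, win, strand = _sense_window(t)
                    i = win.find(m)

    def _plant(t):
        d = int(rng.integers(config.polya_near + 2, config.polya_far - 1))
        motif = motifs[int(rng.integers(0, len(motifs)))]
        arr = genome_arrays[t.chrom]
        if t.strand == "+":
            p0 = t.end - 1 - d
            arr[p0:p0 + 6] = np.frombuffer(motif, dtype=np.uint8)
        else:
            rc = bytes(_COMP[b] for b in reversed(motif))
            p0 = t.start + d - 5
            arr[p0:p0 + 6] = np.frombuffer(rc, dtype=np.uint8)

    ordered = sorted(transcripts, key=lambda t: t.id)
    for t in ordered:
        if not plan[t.id]:
            _scrub(t)
    for t in ordered:
        if plan[t.id]:
            _plant(t)


def truth_eval(
    calls: Mapping[str, str], truth: Mapping[str, str]
) -> pd.DataFrame:
    """Precision/recall per planted class.

    ``calls`` and ``truth`` map the same ids to class labels; a mismatch in id
    sets is an error.
    """
    if set(calls) != set(truth):
        missing = set(truth) ^ set(calls)
        raise ValidationError(f"id mismatch between calls and truth: {sorted(missing)[:5]}")
    classes = sorted(set(truth.values()) | set(calls.values()))
    rows = []
    for cls in classes:
        tp = sum(1 for i in truth if truth[i] == cls and calls[i] == cls)
        fp = sum(1 for i in truth if truth[i] != cls and calls[i] == cls)
        fn = sum(1 for i in truth if truth[i] == cls and calls[i] != cls)
        rows.append(
            {
                "class": cls,
                "n_true": tp + fn,
                "precision": tp / (tp + fp) if tp + fp else float("nan"),
                "recall": tp / (tp + fn) if tp + fn else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["class", "n_true", "precision", "recall"])
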