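"""Intron-chain collapsing, novelty classification and sample sharing.

Transcript identity ignores termini: two models are the same transcript iff
they share chromosome, strand and the ordered list of (donor, acceptor)
splice junctions.  Monoexonic models have an empty chain and are instead
deduplicated by >=50% reciprocal span overlap on the same strand, linked
transitively (single-linkage), since a chain key cannot distinguish them.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .core import (
    Annotation,
    GenomicInterval,
    ScoredTrack,
    TranscriptModel,
    ValidationError,
)

NOVELTY_CATEGORIES = (
    "known",
    "novel_transcript_known_gene",
    "novel_gene_intergenic",
    "antisense_overlap",
    "intronic_overlap",
)


@dataclass(frozen=True)
class IntronChainKey:
    chrom: str
    strand: str
    introns: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        for (d1, a1), (d2, a2) in zip(self.introns, self.introns[1:]):
            if not a1 <= d2:
                raise ValidationError("intron chain must be strictly increasing")

    @property
    def is_monoexonic(self) -> bool:
        return not self.introns


@dataclass
class NoveltyCall:
    model_id: str
    category: str
    matched_reference_ids: List[str] = field(default_factory=list)


@dataclass
class SampleMatrix:
    """Detection flags of merged models across samples.

    ``samples`` is a DataFrame indexed by sample id with columns
    ``tissue``, ``stage`` (adult/embryo) and ``capture`` (pre/post).
    """

    detected: Dict[Tuple[str, str], bool]
    samples: pd.DataFrame
    members: Dict[str, List[str]] = field(default_factory=dict)

    def samples_of(self, model_id: str) -> List[str]:
        return sorted(s for (m, s), v in self.detected.items() if m == model_id and v)


def intron_chain_key(model: TranscriptModel) -> IntronChainKey:
    """The termini-insensitive identity key of a transcript model."""
    return IntronChainKey(model.chrom, model.strand, model.introns)


def _reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def group_by_chain(
    models: Sequence[TranscriptModel], min_mono_overlap: float = 0.5
) -> List[List[TranscriptModel]]:
    """Group models into termini-insensitive identity classes.

    Spliced models group by exact intron-chain key.  Monoexonic models on the
    same chromosome and strand group when their spans overlap reciprocally by
    at least ``min_mono_overlap`` (single-linkage).
    """
    spliced: Dict[IntronChainKey, List[TranscriptModel]] = defaultdict(list)
    mono: Dict[Tuple[str, str], List[TranscriptModel]] = defaultdict(list)
    for m in models:
        key = intron_chain_key(m)
        if key.is_monoexonic:
            mono[(m.chrom, m.strand)].append(m)
        else:
            spliced[key].append(m)

    groups = [spliced[k] for k in sorted(spliced, key=lambda k: (k.chrom, k.strand, k.introns))]
    for cs in sorted(mono):
        ms = sorted(mono[cs], key=lambda m: (m.start, m.end, m.id))
        uf = _UnionFind(len(ms))
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                if ms[j].start >= ms[i].end:
                    break
                if _reciprocal_overlap(
                    (ms[i].start, ms[i].end), (ms[j].start, ms[j].end)
                ) >= min_mono_overlap:
                    uf.union(i, j)
        comp: Dict[int, List[TranscriptModel]] = defaultdict(list)
        for i, m in enumerate(ms):
            comp[uf.find(i)].append(m)
        groups.extend(comp[r] for r in sorted(comp))
    return groups


def merge_models(
    models: Sequence[TranscriptModel],
    sample_of: Optional[Mapping[str, str]] = None,
    samples: Optional[pd.DataFrame] = None,
    id_prefix: str = "merged",
    min_mono_overlap: float = 0.5,
) -> Tuple[Annotation, SampleMatrix]:
    """Collapse models by intron chain, keeping extremal termini.

    ``sample_of`` maps input model id -> sample id (defaults to each model's
    ``sample`` tag, else a single pseudo-sample).  The representative of each
    group takes the 5'-most start and 3'-most end among members, preserving
    the shared internal junction structure.
    """
    if sample_of is None:
        sample_of = {
            m.id: m.tags.get("sample", "sample_1") for m in models
        }
    groups = group_by_chain(models, min_mono_overlap)
    merged: List[TranscriptModel] = []
    detected: Dict[Tuple[str, str], bool] = {}
    members: Dict[str, List[str]] = {}
    for i, group in enumerate(groups):
        rep = group[0]
        start = min(m.start for m in group)
        end = max(m.end for m in group)
        introns = rep.introns
        bounds = [start] + [x for d_a in introns for x in d_a] + [end]
        exons = tuple(zip(bounds[::2], bounds[1::2]))
        mid = f"{id_prefix}_{i + 1:06d}"
        merged.append(
            TranscriptModel(
                id=mid,
                chrom=rep.chrom,
                strand=rep.strand,
                exons=exons,
                gene_id=mid,
                biotype=rep.biotype,
                tags={"members": ",".join(sorted(m.id for m in group))},
            )
        )
        members[mid] = sorted(m.id for m in group)
        for m in group:
            detected[(mid, sample_of[m.id])] = True
    if samples is None:
        sample_ids = sorted({s for (_, s) in detected})
        samples = pd.DataFrame(
            {"tissue": "unknown", "stage": "adult", "capture": "post"},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    ann = Annotation.from_transcripts(merged)
    return ann, SampleMatrix(detected, samples, members)


def classify_novelty(
    model: TranscriptModel,
    reference: Annotation,
    min_mono_overlap: float = 0.5,
) -> NoveltyCall:
    """Classify a model against a reference annotation.

    Precedence: known > same-strand exonic overlap > intronic containment >
    antisense exonic overlap > intergenic.  A monoexonic model is *known*
    when a monoexonic reference transcript on the same strand overlaps it
    reciprocally by >= ``min_mono_overlap``.
    """
    key = intron_chain_key(model)
    same_strand_genes = reference.genes_overlapping_span(
        model.chrom, model.start, model.end, model.strand
    )
    # known: identical intron chain in the reference
    matched = []
    for g in same_strand_genes:
        for t in g.transcripts:
            if key.is_monoexonic:
                if not t.is_spliced and _reciprocal_overlap(
                    (model.start, model.end), (t.start, t.end)
                ) >= min_mono_overlap:
                    matched.append(t.id)
            elif intron_chain_key(t) == key:
                matched.append(t.id)
    if matched:
        return NoveltyCall(model.id, "known", sorted(matched))

    sense_exonic = reference.genes_with_exon_overlap(
        model.chrom, model.exons, model.strand
    )
    if sense_exonic:
        return NoveltyCall(
            model.id, "novel_transcript_known_gene", [g.id for g in sense_exonic]
        )

    containing = [
        g
        for g in same_strand_genes
        if g.start <= model.start and model.end <= g.end
    ]
    if containing:
        return NoveltyCall(model.id, "intronic_overlap", [g.id for g in containing])

    anti = reference.genes_with_exon_overlap(
        model.chrom, model.exons, "-" if model.strand == "+" else "+"
    )
    if anti:
        return NoveltyCall(model.id, "antisense_overlap", [g.id for g in anti])

    return NoveltyCall(model.id, "novel_gene_intergenic", [])


def novelty_report(
    models: Iterable[TranscriptModel], reference: Annotation
) -> pd.DataFrame:
    rows = []
    for m in models:
        call = classify_novelty(m, reference)
        rows.append(
            {
                "model_id": call.model_id,
                "category": call.category,
                "matched_ids": ",".join(call.matched_reference_ids),
            }
        )
    return pd.DataFrame(rows, columns=["model_id", "category", "matched_ids"])


def sample_sharing(matrix: SampleMatrix) -> Dict[str, object]:
    """Per-model sample counts and sharing fractions.

    Returns the fraction of merged models detected in exactly one sample,
    stage-class fractions (adult-only / embryo-only / both) and
    capture-exclusivity fractions (pre-only / post-only / both).
    """
    if not matrix.detected:
        raise ValidationError("empty sample matrix")
    per_model: Dict[str, List[str]] = defaultdict(list)
    for (mid, sid), flag in matrix.detected.items():
        if flag:
            per_model[mid].append(sid)
    n = len(per_model)
    counts = {mid: len(ss) for mid, ss in per_model.items()}
    unique_fraction = sum(1 for c in counts.values() if c == 1) / n

    def _class(mid: str, column: str, a: str, b: str) -> str:
        values = {matrix.samples.loc[s, column] for s in per_model[mid]}
        if values == {a}:
            return f"{a}_only"
        if values == {b}:
            return f"{b}_only"
        return "both"

    stage = {m: _class(m, "stage", "adult", "embryo") for m in per_model}
    capture = {m: _class(m, "capture", "pre", "post") for m in per_model}
    return {
        "n_models": n,
        "sample_counts": counts,
        "unique_fraction": unique_fraction,
        "stage_fractions": {
            k: sum(1 for v in stage.values() if v == k) / n
            for k in ("adult_only", "embryo_only", "both")
        },
        "capture_fractions": {
            k: sum(1 for v in capture.values() if v == k) / n
            for k in ("pre_only", "post_only", "both")
        },
    }


def target_yield(
    targets: ScoredTrack, models: Annotation
) -> Tuple[float, pd.DataFrame]:
    """Fraction of targeted regions detected by >=1 model exon overlap.

    Stranded targets require same-strand exon overlap; unstranded targets
    accept any strand.  Per-class fractions use the target ``label`` as the
    catalog of origin.
    """
    exon_track: Dict[Tuple[str, str], List[Tuple[int, int]]] = defaultdict(list)
    for t in models.transcripts():
        for s, e in t.exons:
            exon_track[(t.chrom, t.strand)].append((s, e))
    trees: Dict[Tuple[str, str], ScoredTrack] = {}
    for key, pairs in exon_track.items():
        trees[key] = ScoredTrack(
            "exons", [GenomicInterval(key[0], s, e, key[1]) for s, e in pairs]
        )

    rows = []
    for iv in targets:
        strands = [iv.strand] if iv.strand in ("+", "-") else ["+", "-"]
        hit = any(
            trees.get((iv.chrom, st)) is not None
            and trees[(iv.chrom, st)].overlapping(iv.chrom, iv.start, iv.end)
            for st in strands
        )
        rows.append({"label": iv.label or "unlabeled", "detected": hit})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("no targets supplied")
    per_class = (
        df.groupby("label")["detected"].agg(["mean", "sum", "count"]).reset_index()
    )
    per_class.columns = ["label", "fraction", "n_detected", "n_targets"]
    return float(df["detected"].mean()), per_class
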