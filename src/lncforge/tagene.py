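"""Acceptance filtering of candidate transcript models against a reference.

Three independent rejection predicates gate a candidate model:

* ``antisense_pc``: >=1 bp exonic overlap with a protein-coding gene's exons
  on the opposite strand;
* ``pseudogene_contained``: the model's genomic span lies entirely within a
  pseudogene locus span (either strand);
* ``low_junction_support``: any intron of the model has short-read support
  below the threshold (default 50 reads; monoexonic models pass vacuously).

The predicates are evaluated independently and all applicable reasons are
recorded per model, so filter ordering can never change the accepted set.
Models whose exons bridge two or more distinct same-strand lncRNA genes are
flagged for manual review but not rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .core import (
    Annotation,
    JunctionSupportTable,
    TranscriptModel,
    ValidationError,
)

REASONS = ("antisense_pc", "pseudogene_contained", "low_junction_support")

LNCRNA_BIOTYPES = {"lncRNA", "lincRNA", "lncrna"}


@dataclass
class FilterConfig:
    min_junction_reads: int = 50
    apply_antisense: bool = True
    apply_pseudogene: bool = True
    apply_junction_support: bool = True
    flag_merges: bool = True

    def __post_init__(self) -> None:
        if self.min_junction_reads < 0:
            raise ValidationError("min_junction_reads must be >= 0")


@dataclass
class FilterReport:
    decisions: Dict[str, str]
    reasons: Dict[str, List[str]]
    merge_flags: List[Tuple[str, Set[str]]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        flagged = {mid: genes for mid, genes in self.merge_flags}
        rows = [
            {
                "model_id": mid,
                "decision": self.decisions[mid],
                "reasons": ",".join(sorted(self.reasons.get(mid, []))),
                "merge_genes": ",".join(sorted(flagged.get(mid, set()))),
            }
            for mid in sorted(self.decisions)
        ]
        return pd.DataFrame(
            rows, columns=["model_id", "decision", "reasons", "merge_genes"]
        )

    @property
    def accepted_ids(self) -> List[str]:
        return sorted(m for m, d in self.decisions.items() if d == "accepted")


def is_antisense_pc(model: TranscriptModel, reference: Annotation) -> bool:
    opposite = "-" if model.strand == "+" else "+"
    hits = reference.genes_with_exon_overlap(model.chrom, model.exons, opposite)
    return any(g.biotype == "protein_coding" for g in hits)


def is_pseudogene_contained(model: TranscriptModel, reference: Annotation) -> bool:
    for g in reference.genes_overlapping_span(model.chrom, model.start, model.end):
        if g.biotype == "pseudogene" and g.start <= model.start and model.end <= g.end:
            return True
    return False


def has_low_junction_support(
    model: TranscriptModel, support: JunctionSupportTable, min_reads: int
) -> bool:
    return any(support.get(j) < min_reads for j in model.junctions)


def _partition(models, predicate):
    kept, removed = [], []
    for m in models:
        (removed if predicate(m) else kept).append(m)
    return kept, removed


def filter_antisense_pc(
    models: Sequence[TranscriptModel], reference: Annotation
) -> Tuple[List[TranscriptModel], List[TranscriptModel]]:
    """(retained, removed) under the antisense-to-protein-coding rule."""
    return _partition(models, lambda m: is_antisense_pc(m, reference))


def filter_pseudogene_contained(
    models: Sequence[TranscriptModel], reference: Annotation
) -> Tuple[List[TranscriptModel], List[TranscriptModel]]:
    """(retained, removed) under strand-agnostic pseudogene span containment."""
    return _partition(models, lambda m: is_pseudogene_contained(m, reference))


def filter_junction_support(
    models: Sequence[TranscriptModel],
    support: JunctionSupportTable,
    min_reads: int = 50,
) -> Tuple[List[TranscriptModel], List[TranscriptModel]]:
    """(retained, removed): removed iff any intron has < ``min_reads`` reads."""
    return _partition(
        models, lambda m: has_low_junction_support(m, support, min_reads)
    )


def flag_locus_merges(
    models: Sequence[TranscriptModel], reference: Annotation
) -> List[Tuple[str, Set[str]]]:
    """Models whose exons overlap exons of >=2 distinct same-strand lncRNA
    genes; these would fuse the genes into one locus if accepted blindly."""
    flags = []
    for m in models:
        hits = reference.genes_with_exon_overlap(m.chrom, m.exons, m.strand)
        lnc = {g.id for g in hits if g.biotype in LNCRNA_BIOTYPES}
        if len(lnc) >= 2:
            flags.append((m.id, lnc))
    return flags


def run_tagene(
    models: Annotation,
    reference: Annotation,
    support: Optional[JunctionSupportTable] = None,
    config: Optional[FilterConfig] = None,
) -> Tuple[Annotation, FilterReport]:
    """Apply the acceptance filters and report per-model decisions.

    Every applicable rejection reason is recorded; a model is accepted iff it
    has none.  Merge flags are reported on all input models, accepted or not.
    """
    config = config or FilterConfig()
    if config.apply_junction_support and support is None:
        raise ValidationError("junction-support filter enabled but no table given")
    all_models = list(models.transcripts())

    reasons: Dict[str, List[str]] = {}
    decisions: Dict[str, str] = {}
    for m in all_models:
        r: List[str] = []
        if config.apply_antisense and is_antisense_pc(m, reference):
            r.append("antisense_pc")
        if config.apply_pseudogene and is_pseudogene_contained(m, reference):
            r.append("pseudogene_contained")
        if config.apply_junction_support and has_low_junction_support(
            m, support, config.min_junction_reads
        ):
            r.append("low_junction_support")
        decisions[m.id] = "rejected" if r else "accepted"
        if r:
            reasons[m.id] = r

    merge_flags = flag_locus_merges(all_models, reference) if config.flag_merges else []
    accepted = Annotation.from_transcripts(
        [m for m in all_models if decisions[m.id] == "accepted"]
    )
    return accepted, FilterReport(decisions, reasons, merge_flags)
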