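"""Cross-species orthology by exon synteny through chain alignments.

A gene's exon union is projected to the other genome through the
best-scoring covering chain per exon (liftover semantics).  A target gene is
a candidate ortholog when its exons overlap a sufficient fraction of the
projected bases *on the correct strand*: the source strand, flipped iff the
chain's target orientation is minus.  Orthology calls require strict
reciprocity — an edge a-b exists only when b is a candidate of a through the
A->B chains and a is a candidate of b through the B->A chains — and connected
components of the resulting bipartite graph are labeled 1:1, 1:many, many:1
or many:many.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .core import (
    Annotation,
    ChainAlignment,
    GeneLocus,
    GenomicInterval,
    ValidationError,
    flip_strand,
    merge_intervals,
)


@dataclass
class OrthologyParams:
    min_exon_overlap_fraction: float = 0.5
    min_exons_mapped: float = 0.5

    def __post_init__(self) -> None:
        for v in (self.min_exon_overlap_fraction, self.min_exons_mapped):
            if not (0 < v <= 1):
                raise ValidationError("fractions must lie in (0, 1]")


@dataclass
class ProjectionResult:
    source: GenomicInterval
    fragments: List[GenomicInterval] = field(default_factory=list)

    @property
    def mapped_bp(self) -> int:
        return sum(len(f) for f in self.fragments)

    @property
    def mapped_fraction(self) -> float:
        return self.mapped_bp / len(self.source)


@dataclass
class OrthologyCall:
    gene_a: str
    gene_b: List[str]
    category: str  # one_to_one | one_to_many | many_to_one | many_to_many | none
    fractions: Dict[str, float] = field(default_factory=dict)


def project_interval(chain: ChainAlignment, iv: GenomicInterval) -> ProjectionResult:
    """Project an interval through one chain; gap bases are dropped.

    For minus-orientation chains the block's target coordinates (which the
    chain stores on the reversed target sequence) are converted to forward
    coordinates and the fragment strand is flipped.
    """
    result = ProjectionResult(iv)
    if iv.chrom != chain.s_chrom:
        return result
    for ss, ts, ln in chain.blocks:
        lo = max(iv.start, ss)
        hi = min(iv.end, ss + ln)
        if lo >= hi:
            continue
        t0 = ts + (lo - ss)
        t1 = ts + (hi - ss)
        if chain.t_orient == "+":
            frag = GenomicInterval(chain.t_chrom, t0, t1, iv.strand)
        else:
            frag = GenomicInterval(
                chain.t_chrom,
                chain.t_size - t1,
                chain.t_size - t0,
                flip_strand(iv.strand),
            )
        result.fragments.append(frag)
    return result


def project_interval_per_base(
    chain: ChainAlignment, iv: GenomicInterval
) -> List[Tuple[int, int, str]]:
    """Brute-force per-base projection: (source_pos, target_forward_pos,
    target_strand) for every mapped base.  Test oracle for
    :func:`project_interval`; intentionally naive."""
    out = []
    if iv.chrom != chain.s_chrom:
        return out
    for pos in range(iv.start, iv.end):
        for ss, ts, ln in chain.blocks:
            if ss <= pos < ss + ln:
                t = ts + (pos - ss)
                if chain.t_orient == "+":
                    out.append((pos, t, iv.strand))
                else:
                    out.append((pos, chain.t_size - 1 - t, flip_strand(iv.strand)))
                break
    return out


@dataclass
class GeneProjection:
    gene_id: str
    fragments: List[GenomicInterval]
    n_exons: int
    n_exons_mapped: int
    per_exon_fraction: List[float]

    @property
    def exons_mapped_fraction(self) -> float:
        return self.n_exons_mapped / self.n_exons if self.n_exons else 0.0

    @property
    def projected_bp(self) -> int:
        return sum(len(f) for f in self.fragments)


def project_gene(
    gene: GeneLocus,
    chains: Sequence[ChainAlignment],
    params: Optional[OrthologyParams] = None,
) -> GeneProjection:
    """Project the gene's exon union through the best covering chain per exon.

    When several chains map an exon, the one with the highest score (ties
    broken by chain id) wins for that exon.
    """
    exons = gene.exon_union()
    by_chrom = [c for c in chains if c.s_chrom == gene.chrom]
    fragments: List[GenomicInterval] = []
    per_exon: List[float] = []
    n_mapped = 0
    for s, e in exons:
        iv = GenomicInterval(gene.chrom, s, e, gene.strand)
        best: Optional[ProjectionResult] = None
        best_key = None
        for chain in by_chrom:
            res = project_interval(chain, iv)
            if not res.fragments:
                continue
            key = (chain.score, chain.chain_id)
            if best is None or key > best_key:
                best, best_key = res, key
        if best is None:
            per_exon.append(0.0)
            continue
        n_mapped += 1
        per_exon.append(best.mapped_fraction)
        fragments.extend(best.fragments)
    return GeneProjection(gene.id, fragments, len(exons), n_mapped, per_exon)


def candidate_orthologs(
    gene: GeneLocus,
    target: Annotation,
    chains: Sequence[ChainAlignment],
    params: Optional[OrthologyParams] = None,
) -> List[Tuple[str, float]]:
    """Target genes overlapping the projected exons on the correct strand.

    Returns (gene id, overlapped projected bp / total projected bp) for
    candidates passing ``min_exon_overlap_fraction``; empty when fewer than
    ``min_exons_mapped`` of the gene's exons project at all.
    """
    params = params or OrthologyParams()
    proj = project_gene(gene, chains, params)
    if proj.projected_bp == 0 or proj.exons_mapped_fraction < params.min_exons_mapped:
        return []
    overlap_bp: Dict[str, int] = defaultdict(int)
    # deduplicate projected bases per (chrom, strand) before overlap counting
    frag_by_cs: Dict[Tuple[str, str], List[Tuple[int, int]]] = defaultdict(list)
    for f in proj.fragments:
        frag_by_cs[(f.chrom, f.strand)].append((f.start, f.end))
    total_bp = 0
    for (chrom, strand), pairs in frag_by_cs.items():
        merged = merge_intervals(pairs)
        total_bp += sum(e - s for s, e in merged)
        for s, e in merged:
            for g in target.genes_with_exon_overlap(chrom, [(s, e)], strand):
                for gs, ge in g.exon_union():
                    ov = min(e, ge) - max(s, gs)
                    if ov > 0:
                        overlap_bp[g.id] += ov
    out = [
        (gid, bp / total_bp)
        for gid, bp in overlap_bp.items()
        if bp / total_bp >= params.min_exon_overlap_fraction
    ]
    return sorted(out, key=lambda x: (-x[1], x[0]))


def _component_category(n_a: int, n_b: int) -> str:
    if n_a == 1 and n_b == 1:
        return "one_to_one"
    if n_a == 1:
        return "one_to_many"
    if n_b == 1:
        return "many_to_one"
    return "many_to_many"


def reciprocal_orthology(
    annot_a: Annotation,
    annot_b: Annotation,
    chains_ab: Sequence[ChainAlignment],
    chains_ba: Sequence[ChainAlignment],
    params: Optional[OrthologyParams] = None,
) -> List[OrthologyCall]:
    """Strict reciprocal orthology calls for every gene of ``annot_a``.

    The call category is derived from the connected component of the
    reciprocal bipartite graph containing the gene.
    """
    params = params or OrthologyParams()
    cand_ab: Dict[str, Dict[str, float]] = {}
    for g in sorted(annot_a, key=lambda g: g.id):
        cand_ab[g.id] = dict(candidate_orthologs(g, annot_b, chains_ab, params))
    cand_ba: Dict[str, Dict[str, float]] = {}
    for g in sorted(annot_b, key=lambda g: g.id):
        cand_ba[g.id] = dict(candidate_orthologs(g, annot_a, chains_ba, params))

    edges: Dict[str, set] = defaultdict(set)  # a -> {b}
    redges: Dict[str, set] = defaultdict(set)
    for a, bs in cand_ab.items():
        for b in bs:
            if a in cand_ba.get(b, {}):
                edges[a].add(b)
                redges[b].add(a)

    # connected components of the bipartite graph
    comp_of_a: Dict[str, int] = {}
    comp_members: Dict[int, Tuple[set, set]] = {}
    comp_id = 0
    for a in sorted(edges):
        if a in comp_of_a:
            continue
        a_side, b_side = set(), set()
        stack = [("a", a)]
        while stack:
            side, node = stack.pop()
            if side == "a":
                if node in a_side:
                    continue
                a_side.add(node)
                stack.extend(("b", b) for b in edges[node])
            else:
                if node in b_side:
                    continue
                b_side.add(node)
                stack.extend(("a", x) for x in redges[node])
        for x in a_side:
            comp_of_a[x] = comp_id
        comp_members[comp_id] = (a_side, b_side)
        comp_id += 1

    calls = []
    for g in sorted(annot_a, key=lambda g: g.id):
        bs = sorted(edges.get(g.id, ()))
        if not bs:
            calls.append(OrthologyCall(g.id, [], "none"))
            continue
        a_side, b_side = comp_members[comp_of_a[g.id]]
        category = _component_category(len(a_side), len(b_side))
        calls.append(
            OrthologyCall(
                g.id,
                bs,
                category,
                {b: cand_ab[g.id][b] for b in bs},
            )
        )
    return calls


def calls_to_frame(calls: Iterable[OrthologyCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        if c.gene_b:
            for b in c.gene_b:
                rows.append(
                    {
                        "gene_a": c.gene_a,
                        "gene_b": b,
                        "category": c.category,
                        "fraction_ab": c.fractions.get(b, float("nan")),
                    }
                )
        else:
            rows.append(
                {"gene_a": c.gene_a, "gene_b": "", "category": "none",
                 "fraction_ab": float("nan")}
            )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "category", "fraction_ab"])


def disease_ortholog_lookup(
    calls: Sequence[OrthologyCall], disease_genes: Sequence[str]
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Orthology status of a clinically relevant gene list.

    Unmatched ids are reported with category ``not_in_annotation``; the
    aggregate counts the listed genes with >=1 ortholog.
    """
    by_id = {c.gene_a: c for c in calls}
    rows = []
    n_with = 0
    for gid in disease_genes:
        c = by_id.get(gid)
        if c is None:
            rows.append({"gene_id": gid, "category": "not_in_annotation",
                         "partners": ""})
            continue
        if c.gene_b:
            n_with += 1
        rows.append(
            {"gene_id": gid, "category": c.category,
             "partners": ",".join(c.gene_b)}
        )
    df = pd.DataFrame(rows, columns=["gene_id", "category", "partners"])
    summary = {
        "n_listed": len(disease_genes),
        "n_with_ortholog": n_with,
        "fraction_with_ortholog": (
            n_with / len(disease_genes) if disease_genes else float("nan")
        ),
    }
    return df, summary
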