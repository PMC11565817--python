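"""Core domain types shared by every pipeline stage.

All coordinates are 0-based, half-open ``[start, end)`` on the forward
strand of the chromosome.  Conversion to and from 1-based-inclusive (GTF)
or reversed-strand (chain file) conventions happens only in :mod:`lncforge.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval with optional score and label.

    ``strand`` may be ``.`` only on evidence tracks; transcripts are always
    stranded.  Intervals order by ``(chrom, start, end, strand)``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def sort_key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def flip_strand(strand: str) -> str:
    return {"+": "-", "-": "+", ".": "."}[strand]


@dataclass(frozen=True)
class SpliceJunction:
    """An intron: ``donor`` is the first intronic base (0-based), ``acceptor``
    the exclusive intron end.  Keyed by (chrom, strand, donor, acceptor)."""

    chrom: str
    strand: str
    donor: int
    acceptor: int

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValidationError(
                f"junction donor {self.donor} must precede acceptor {self.acceptor}"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded multi-exon transcript model.

    ``exons`` are sorted, non-overlapping, non-adjacent ``(start, end)``
    pairs.  ``tags`` carries free-form provenance (sample of origin, decoy
    source, ...) and does not participate in equality.
    """

    id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    gene_id: Optional[str] = None
    biotype: str = "other"
    tags: Mapping[str, str] = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.id}: strand must be + or -, got {self.strand!r}"
            )
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        if len(exons) < 1:
            raise ValidationError(f"transcript {self.id}: needs >= 1 exon")
        for s, e in exons:
            if not (0 <= s < e):
                raise ValidationError(
                    f"transcript {self.id}: bad exon ({s}, {e})"
                )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if not e1 < s2:
                raise ValidationError(
                    f"transcript {self.id}: exons must be sorted, disjoint and "
                    f"non-adjacent; got ({s1},{e1}) then ({s2},{e2})"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """(donor, acceptor) pairs; empty iff monoexonic."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def junctions(self) -> Tuple[SpliceJunction, ...]:
        return tuple(
            SpliceJunction(self.chrom, self.strand, d, a) for d, a in self.introns
        )

    @property
    def is_spliced(self) -> bool:
        return len(self.exons) > 1

    @property
    def tss(self) -> int:
        """5' position: first covered base on +, last covered base on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """3'-terminal base position."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneLocus:
    """A gene: same-chromosome, same-strand transcripts plus a biotype."""

    id: str
    biotype: str
    chrom: str
    strand: str
    transcripts: List[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise ValidationError(
                    f"gene {self.id}: transcript {t.id} on "
                    f"{t.chrom}{t.strand}, gene on {self.chrom}{self.strand}"
                )

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def exon_union(self) -> List[Tuple[int, int]]:
        """Merged union of all member transcripts' exons."""
        return merge_intervals(
            [e for t in self.transcripts for e in t.exons]
        )


def merge_intervals(pairs: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of (start, end) pairs as a sorted list of disjoint pairs."""
    out: List[Tuple[int, int]] = []
    for s, e in sorted(pairs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class Annotation:
    """An indexed collection of gene loci.

    Builds lazy per-chromosome interval indexes over gene spans and exons so
    overlap queries stay sublinear at realistic locus counts.
    """

    def __init__(self, genes: Optional[Iterable[GeneLocus]] = None) -> None:
        self.genes: Dict[str, GeneLocus] = {}
        self._span_index: Optional[Dict[str, IntervalTree]] = None
        self._exon_index: Optional[Dict[str, IntervalTree]] = None
        for g in genes or ():
            self.add_gene(g)

    def add_gene(self, gene: GeneLocus) -> None:
        if gene.id in self.genes:
            raise ValidationError(f"duplicate gene id {gene.id}")
        self.genes[gene.id] = gene
        self._span_index = None
        self._exon_index = None

    @classmethod
    def from_transcripts(
        cls, transcripts: Iterable[TranscriptModel], biotype: str = "other"
    ) -> "Annotation":
        """Group transcripts into loci by ``gene_id`` (falling back to the
        transcript id for orphans)."""
        by_gene: Dict[str, List[TranscriptModel]] = {}
        order: List[str] = []
        for t in transcripts:
            gid = t.gene_id or t.id
            if gid not in by_gene:
                by_gene[gid] = []
                order.append(gid)
            by_gene[gid].append(t)
        ann = cls()
        for gid in order:
            ts = by_gene[gid]
            bt = ts[0].biotype or biotype
            ann.add_gene(GeneLocus(gid, bt, ts[0].chrom, ts[0].strand, ts))
        return ann

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self.genes.values():
            yield from g.transcripts

    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneLocus]:
        return iter(self.genes.values())

    # ---- overlap indexes -------------------------------------------------

    def _spans(self) -> Dict[str, IntervalTree]:
        if self._span_index is None:
            idx: Dict[str, IntervalTree] = {}
            for g in self.genes.values():
                idx.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
            self._span_index = idx
        return self._span_index

    def _exons(self) -> Dict[str, IntervalTree]:
        if self._exon_index is None:
            idx: Dict[str, IntervalTree] = {}
            for g in self.genes.values():
                tree = idx.setdefault(g.chrom, IntervalTree())
                for s, e in g.exon_union():
                    tree.addi(s, e, g)
            self._exon_index = idx
        return self._exon_index

    def genes_overlapping_span(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> List[GeneLocus]:
        tree = self._spans().get(chrom)
        if tree is None:
            return []
        hits = {iv.data.id: iv.data for iv in tree.overlap(start, end)}
        out = [g for g in hits.values() if strand is None or g.strand == strand]
        return sorted(out, key=lambda g: g.id)

    def genes_with_exon_overlap(
        self,
        chrom: str,
        exons: Sequence[Tuple[int, int]],
        strand: Optional[str] = None,
    ) -> List[GeneLocus]:
        """Genes with >=1 bp exon-exon overlap with any of ``exons``."""
        tree = self._exons().get(chrom)
        if tree is None:
            return []
        hits: Dict[str, GeneLocus] = {}
        for s, e in exons:
            for iv in tree.overlap(s, e):
                g = iv.data
                if strand is None or g.strand == strand:
                    hits[g.id] = g
        return sorted(hits.values(), key=lambda g: g.id)


class JunctionSupportTable:
    """Read counts supporting splice junctions; absent junction means 0."""

    def __init__(
        self, counts: Optional[Mapping[SpliceJunction, int]] = None
    ) -> None:
        self._counts: Dict[SpliceJunction, int] = {}
        for j, c in (counts or {}).items():
            self.set(j, c)

    def set(self, junction: SpliceJunction, count: int) -> None:
        if count < 0:
            raise ValidationError(
                f"negative junction count {count} for {junction}"
            )
        self._counts[junction] = int(count)

    def get(self, junction: SpliceJunction) -> int:
        return self._counts.get(junction, 0)

    def items(self):
        return self._counts.items()

    def __len__(self) -> int:
        return len(self._counts)


class ScoredTrack:
    """A named interval track (CAGE clusters, cCREs, TF peaks, GWAS hits...).

    Input order is preserved in ``intervals``; queries go through a sorted
    per-chromosome index built lazily.
    """

    def __init__(self, name: str, intervals: Optional[Iterable[GenomicInterval]] = None):
        self.name = name
        self.intervals: List[GenomicInterval] = list(intervals or ())
        self._by_chrom: Optional[Dict[str, Tuple[np.ndarray, np.ndarray, list]]] = None

    def add(self, iv: GenomicInterval) -> None:
        self.intervals.append(iv)
        self._by_chrom = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def _index(self) -> Dict[str, Tuple[np.ndarray, np.ndarray, list]]:
        if self._by_chrom is None:
            grouped: Dict[str, list] = {}
            for iv in self.intervals:
                grouped.setdefault(iv.chrom, []).append(iv)
            idx = {}
            for chrom, ivs in grouped.items():
                ivs.sort(key=lambda x: (x.start, x.end))
                starts = np.array([iv.start for iv in ivs], dtype=np.int64)
                ends = np.array([iv.end for iv in ivs], dtype=np.int64)
                idx[chrom] = (starts, ends, ivs)
            self._by_chrom = idx
        return self._by_chrom

    def overlapping(self, chrom: str, start: int, end: int) -> List[GenomicInterval]:
        """All intervals overlapping [start, end)."""
        got = self._index().get(chrom)
        if got is None:
            return []
        starts, ends, ivs = got
        # candidates: start < end_query; filter by end > start_query
        hi = int(np.searchsorted(starts, end, side="left"))
        return [ivs[i] for i in range(hi) if ends[i] > start]

    def nearest_edge_distance(self, chrom: str, pos: int, strand: Optional[str] = None) -> Optional[int]:
        """Distance from ``pos`` to the nearest interval edge (0 if covered).

        When ``strand`` is given, only intervals on that strand or unstranded
        ones are considered.
        """
        got = self._index().get(chrom)
        if got is None:
            return None
        best: Optional[int] = None
        for iv in got[2]:
            if strand is not None and iv.strand != "." and iv.strand != strand:
                continue
            if iv.start <= pos < iv.end:
                return 0
            d = (iv.start - pos) if pos < iv.start else (pos - (iv.end - 1))
            if best is None or d < best:
                best = d
        return best

    def merged(self, chrom: str) -> List[Tuple[int, int]]:
        got = self._index().get(chrom)
        if got is None:
            return []
        return merge_intervals([(iv.start, iv.end) for iv in got[2]])

    def chroms(self) -> List[str]:
        return sorted(self._index().keys())


class GenomeSequence:
    """chrom -> uppercase nucleotide string over {A, C, G, T, N}."""

    COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

    def __init__(self, seqs: Mapping[str, str]):
        self.seqs: Dict[str, str] = {c: s.upper() for c, s in seqs.items()}
        for c, s in self.seqs.items():
            bad = set(s) - set("ACGTN")
            if bad:
                raise ValidationError(
                    f"chromosome {c}: invalid characters {sorted(bad)}"
                )

    @property
    def sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        s = self.seqs[chrom]
        if not (0 <= start <= end <= len(s)):
            raise ValidationError(
                f"query {chrom}:{start}-{end} outside sequence of length {len(s)}"
            )
        sub = s[start:end]
        if strand == "-":
            sub = sub.translate(self.COMPLEMENT)[::-1]
        return sub


@dataclass
class ChainAlignment:
    """An ungapped-block pairwise alignment (UCSC chain semantics).

    ``blocks`` are ``(source_start, target_start, length)`` with strictly
    increasing source and target offsets.  When ``t_orient`` is ``-``, target
    coordinates live on the reversed target sequence, exactly as in the chain
    file; :func:`lncforge.orthology.project_interval` converts to forward
    coordinates.
    """

    s_chrom: str
    s_size: int
    t_chrom: str
    t_size: int
    t_orient: str
    blocks: List[Tuple[int, int, int]]
    chain_id: str = "1"
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.t_orient not in ("+", "-"):
            raise ValidationError(f"chain {self.chain_id}: bad orientation")
        prev_s = prev_t = -1
        for ss, ts, ln in self.blocks:
            if ln <= 0 or ss < 0 or ts < 0:
                raise ValidationError(f"chain {self.chain_id}: bad block ({ss},{ts},{ln})")
            if ss < prev_s or ts < prev_t:
                raise ValidationError(
                    f"chain {self.chain_id}: blocks must be increasing"
                )
            prev_s, prev_t = ss + ln, ts + ln
            if prev_s > self.s_size or prev_t > self.t_size:
                raise ValidationError(
                    f"chain {self.chain_id}: block ({ss},{ts},{ln}) exceeds "
                    "declared chromosome size"
                )

    @property
    def s_start(self) -> int:
        return self.blocks[0][0]

    @property
    def s_end(self) -> int:
        b = self.blocks[-1]
        return b[0] + b[2]
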