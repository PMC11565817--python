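"""Evaluation of transcript sets against functional-genomics evidence.

Each operation takes an annotation (or its TSS set) plus one evidence track
and returns a support summary or a positional profile, so the same code runs
on novel models, previously annotated genes and decoy background sets.

Distance conventions (each matching the evidence type):

* TSS vs CAGE-like clusters: nearest cluster *edge*, supported within
  +/- ``window`` bp (default 50), inclusive;
* TSS vs cCREs: distance to the cCRE *center*, supported strictly below
  ``max_dist`` (default 2000 bp);
* polyadenylation motif: motif start 10-50 bp upstream of the 3' end on the
  transcript's sense strand, bounds inclusive.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    Annotation,
    GenomeSequence,
    GenomicInterval,
    ScoredTrack,
    ValidationError,
    merge_intervals,
)

CCRE_CLASSES = ("PLS", "pELS", "dELS", "CA-H3K4me3", "CA-CTCF", "CA-TF", "CA", "TF")

POLYA_MOTIFS = ("AATAAA", "ATTAAA")


@dataclass(frozen=True)
class Tss:
    chrom: str
    pos: int
    strand: str


@dataclass
class TssSet:
    """Unique transcription start positions with transcript back-references."""

    positions: Dict[Tss, List[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self):
        return iter(sorted(self.positions, key=lambda t: (t.chrom, t.pos, t.strand)))


@dataclass
class SupportSummary:
    name: str
    numerator: int
    denominator: int
    breakdown: Dict[str, float] = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator if self.denominator else float("nan")


def extract_tss(annotation: Annotation) -> TssSet:
    """Strand-aware 5' positions, deduplicated by exact (chrom, pos, strand)."""
    out: Dict[Tss, List[str]] = {}
    for t in annotation.transcripts():
        key = Tss(t.chrom, t.tss, t.strand)
        out.setdefault(key, []).append(t.id)
    return TssSet(out)


def tss_support(
    tss: TssSet,
    evidence: Sequence[ScoredTrack],
    window: int = 50,
    stranded: bool = True,
) -> SupportSummary:
    """Fraction of TSSs within ``window`` bp of an evidence interval edge.

    A TSS covered by an interval has distance 0.  Stranded evidence intervals
    must match the TSS strand when ``stranded``; unstranded intervals ('.')
    always qualify.  The breakdown carries one fraction per track plus 'any'.
    """
    n = len(tss)
    per_track = {tr.name: 0 for tr in evidence}
    any_count = 0
    for t in tss:
        hit_any = False
        for tr in evidence:
            d = tr.nearest_edge_distance(
                t.chrom, t.pos, t.strand if stranded else None
            )
            if d is not None and d <= window:
                per_track[tr.name] += 1
                hit_any = True
        if hit_any:
            any_count += 1
    breakdown = {name: (c / n if n else float("nan")) for name, c in per_track.items()}
    return SupportSummary("tss_support", any_count, n, breakdown)


def polya_support(
    annotation: Annotation,
    genome: GenomeSequence,
    motifs: Sequence[str] = POLYA_MOTIFS,
    near: int = 10,
    far: int = 50,
) -> SupportSummary:
    """Transcripts whose 3' end has a polyadenylation motif 10-50 bp upstream.

    The motif must occur on the transcript's sense strand with its first base
    ``d`` bases upstream of the 3'-terminal base, ``near <= d <= far``.
    """
    n = 0
    supported = 0
    for t in annotation.transcripts():
        n += 1
        if transcript_has_polya(t, genome, motifs, near, far):
            supported += 1
    return SupportSummary("polya_support", supported, n)


def transcript_has_polya(
    t, genome: GenomeSequence, motifs: Sequence[str] = POLYA_MOTIFS,
    near: int = 10, far: int = 50,
) -> bool:
    size = genome.sizes[t.chrom]
    if t.strand == "+":
        lo = max(0, t.end - (far + 1))
        window = genome.fetch(t.chrom, lo, t.end)
    else:
        hi = min(size, t.start + far + 1)
        window = genome.fetch(t.chrom, t.start, hi, strand="-")
    # window is the sense-strand sequence ending at the 3'-terminal base
    L = len(window)
    for motif in motifs:
        start = 0
        while True:
            i = window.find(motif, start)
            if i < 0:
                break
            d = (L - 1) - i  # upstream offset of the motif start
            if near <= d <= far:
                return True
            start = i + 1
    return False


# --------------------------------------------------------------------------
# cCREs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CcreRecord:
    interval: GenomicInterval
    label: str

    def __post_init__(self) -> None:
        if self.label not in CCRE_CLASSES:
            raise ValidationError(f"unknown cCRE class {self.label!r}")

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


def ccres_from_track(track: ScoredTrack) -> List[CcreRecord]:
    return [CcreRecord(iv, iv.label) for iv in track]


def _tss_positions_by_chrom(tss: TssSet) -> Dict[str, np.ndarray]:
    by_chrom: Dict[str, List[int]] = defaultdict(list)
    for t in tss:
        by_chrom[t.chrom].append(t.pos)
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in by_chrom.items()}


def _min_dist(sorted_pos: np.ndarray, x: int) -> int:
    i = int(np.searchsorted(sorted_pos, x))
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(sorted_pos):
            d = abs(int(sorted_pos[j]) - x)
            best = d if best is None else min(best, d)
    return best if best is not None else np.iinfo(np.int64).max


def ccre_support(
    tss: TssSet, ccres: Sequence[CcreRecord], max_dist: int = 2000
) -> SupportSummary:
    """Per-class fraction of TSSs with a cCRE center strictly closer than
    ``max_dist``; 'any' pools every class."""
    n = len(tss)
    centers: Dict[str, Dict[str, list]] = defaultdict(lambda: defaultdict(list))
    for r in ccres:
        centers[r.label][r.interval.chrom].append(r.center)
    arr = {
        label: {c: np.array(sorted(v), dtype=np.int64) for c, v in chroms.items()}
        for label, chroms in centers.items()
    }
    counts = {label: 0 for label in arr}
    any_count = 0
    for t in tss:
        hit = False
        for label, chroms in arr.items():
            pos = chroms.get(t.chrom)
            if pos is not None and len(pos) and _min_dist(pos, t.pos) < max_dist:
                counts[label] += 1
                hit = True
        if hit:
            any_count += 1
    breakdown = {label: (c / n if n else float("nan")) for label, c in counts.items()}
    return SupportSummary("ccre_support", any_count, n, breakdown)


def reclassify_ccres(
    ccres: Sequence[CcreRecord],
    tss: TssSet,
    promoter_dist: int = 200,
    enhancer_dist: int = 2000,
) -> Tuple[List[CcreRecord], Counter]:
    """TSS-proximity-dependent reclassification.

    Only two transitions are permitted: CA-H3K4me3 -> PLS when the center is
    strictly within ``promoter_dist`` of a TSS, and dELS -> pELS within
    ``enhancer_dist``.  Record count is conserved and the operation is
    idempotent for a fixed TSS set.
    """
    tss_pos = _tss_positions_by_chrom(tss)
    out: List[CcreRecord] = []
    transitions: Counter = Counter()
    for r in ccres:
        pos = tss_pos.get(r.interval.chrom)
        d = _min_dist(pos, r.center) if pos is not None and len(pos) else None
        new_label = r.label
        if r.label == "CA-H3K4me3" and d is not None and d < promoter_dist:
            new_label = "PLS"
        elif r.label == "dELS" and d is not None and d < enhancer_dist:
            new_label = "pELS"
        transitions[(r.label, new_label)] += 1
        out.append(r if new_label == r.label else CcreRecord(r.interval, new_label))
    return out, transitions


def class_proportions(ccres: Sequence[CcreRecord]) -> Dict[str, float]:
    counts = Counter(r.label for r in ccres)
    n = sum(counts.values())
    return {label: counts.get(label, 0) / n for label in CCRE_CLASSES} if n else {}


# --------------------------------------------------------------------------
# TF coverage profile
# --------------------------------------------------------------------------

def _coverage_index(pairs: List[Tuple[int, int]]):
    """(starts, ends, cumulative covered length before each interval)."""
    starts = np.array([p[0] for p in pairs], dtype=np.int64)
    ends = np.array([p[1] for p in pairs], dtype=np.int64)
    lens = ends - starts
    cum = np.concatenate([[0], np.cumsum(lens)])
    return starts, ends, cum


def _covered_bp(idx, s: int, e: int) -> int:
    starts, ends, cum = idx
    i = int(np.searchsorted(ends, s, side="right"))
    j = int(np.searchsorted(starts, e, side="left"))
    if i >= j:
        return 0
    total = int(cum[j] - cum[i])
    total -= max(0, s - int(starts[i]))
    total -= max(0, int(ends[j - 1]) - e)
    return total


def tf_coverage_profile(
    tss: TssSet,
    peaks_by_tf: Mapping[str, ScoredTrack],
    flank: int = 5000,
    window: int = 500,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Strand-oriented peak-coverage profile around TSSs, averaged over TFs.

    Windows tile offsets [-flank, +flank) in steps of ``window`` (negative =
    upstream).  For each TF, each window's value is the mean over TSSs of the
    fraction of window bases covered by the TF's merged peaks; the profile is
    the mean over TFs.  Also returns the per-TSS count of distinct TFs with a
    peak overlapping the TSS position itself.
    """
    if not peaks_by_tf:
        raise ValidationError("need at least one TF track")
    if (2 * flank) % window != 0:
        raise ValidationError("window must divide 2*flank")
    n_win = 2 * flank // window
    offsets = [-flank + k * window for k in range(n_win)]
    tss_list = list(tss)
    n_tss = len(tss_list)

    merged_idx: Dict[str, Dict[str, tuple]] = {}
    for tf, track in peaks_by_tf.items():
        merged_idx[tf] = {
            chrom: _coverage_index(track.merged(chrom)) for chrom in track.chroms()
        }

    per_tf = {}
    tf_counts = pd.Series(0, index=range(n_tss), dtype=int)
    for tf in sorted(peaks_by_tf):
        idx_by_chrom = merged_idx[tf]
        win_sums = np.zeros(n_win)
        for ti, t in enumerate(tss_list):
            idx = idx_by_chrom.get(t.chrom)
            if idx is None:
                continue
            if _covered_bp(idx, t.pos, t.pos + 1) > 0:
                tf_counts[ti] += 1
            for k, off in enumerate(offsets):
                if t.strand == "+":
                    s, e = t.pos + off, t.pos + off + window
                else:
                    s, e = t.pos - off - window + 1, t.pos - off + 1
                s = max(0, s)
                if e <= s:
                    continue
                win_sums[k] += _covered_bp(idx, s, e) / window
        per_tf[tf] = win_sums / n_tss if n_tss else win_sums
    profile = pd.DataFrame(per_tf, index=pd.Index(offsets, name="window_start"))
    profile["mean_coverage"] = profile.mean(axis=1)
    return profile, tf_counts


# --------------------------------------------------------------------------
# GWAS
# --------------------------------------------------------------------------

def _region_bases(
    loci: Annotation,
    region: str,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> Dict[str, List[Tuple[int, int]]]:
    spans: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    if region in ("gene_body", "complement"):
        for g in loci:
            spans[g.chrom].append((g.start, g.end))
    elif region == "exons":
        for g in loci:
            spans[g.chrom].extend(g.exon_union())
    else:
        raise ValidationError(f"unknown region {region!r}")
    merged = {c: merge_intervals(v) for c, v in spans.items()}
    if region != "complement":
        return merged
    if chrom_sizes is None:
        raise ValidationError("complement region requires chrom_sizes")
    out: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, size in chrom_sizes.items():
        prev = 0
        pieces = []
        for s, e in merged.get(chrom, []):
            if s > prev:
                pieces.append((prev, s))
            prev = max(prev, e)
        if prev < size:
            pieces.append((prev, size))
        out[chrom] = pieces
    return out


def gwas_density(
    loci: Annotation,
    hits: ScoredTrack,
    region: str = "gene_body",
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> float:
    """GWAS hits per 100 kb of the region's (deduplicated) base set.

    Hits are strand-agnostic point positions; every record falling in the
    region counts, duplicated positions once per record.
    """
    bases = _region_bases(loci, region, chrom_sizes)
    total_len = sum(e - s for pairs in bases.values() for s, e in pairs)
    if total_len == 0:
        raise ValidationError(f"region {region!r} has zero length")
    arrs = {
        c: (np.array([s for s, _ in pairs], dtype=np.int64),
            np.array([e for _, e in pairs], dtype=np.int64))
        for c, pairs in bases.items()
    }
    n_in = 0
    for iv in hits:
        got = arrs.get(iv.chrom)
        if got is None:
            continue
        starts, ends = got
        i = int(np.searchsorted(starts, iv.start, side="right")) - 1
        if i >= 0 and iv.start < ends[i]:
            n_in += 1
    return n_in / total_len * 1e5


def gwas_profile(
    loci: Annotation,
    hits: ScoredTrack,
    flank: int = 15000,
    n_body_bins: int = 20,
    flank_bin: int = 1000,
) -> pd.DataFrame:
    """Meta-gene GWAS density profile: absolute-bp flank bins plus gene bodies
    rescaled to ``n_body_bins`` meta-bins, strand-oriented (upstream first).

    Density in each bin is pooled hits / pooled bin length, per 100 kb.
    """
    if flank % flank_bin != 0:
        raise ValidationError("flank_bin must divide flank")
    n_flank = flank // flank_bin
    labels = (
        [f"up_{i}" for i in range(n_flank)]
        + [f"body_{i}" for i in range(n_body_bins)]
        + [f"down_{i}" for i in range(n_flank)]
    )
    hit_counts = np.zeros(len(labels))
    bin_lengths = np.zeros(len(labels))

    hits_by_chrom: Dict[str, np.ndarray] = defaultdict(lambda: np.array([], dtype=np.int64))
    grouped: Dict[str, List[int]] = defaultdict(list)
    for iv in hits:
        grouped[iv.chrom].append(iv.start)
    for c, v in grouped.items():
        hits_by_chrom[c] = np.array(sorted(v), dtype=np.int64)

    def count_in(chrom: str, s: int, e: int) -> int:
        pos = hits_by_chrom.get(chrom)
        if pos is None or s >= e:
            return 0
        return int(np.searchsorted(pos, e, side="left") - np.searchsorted(pos, s, side="left"))

    for g in loci:
        # genomic bins 5'->3' in gene orientation
        bins: List[Tuple[int, int]] = []
        if g.strand == "+":
            for i in range(n_flank):
                bins.append((g.start - flank + i * flank_bin, g.start - flank + (i + 1) * flank_bin))
            edges = np.linspace(g.start, g.end, n_body_bins + 1).astype(int)
            bins.extend(zip(edges[:-1], edges[1:]))
            for i in range(n_flank):
                bins.append((g.end + i * flank_bin, g.end + (i + 1) * flank_bin))
        else:
            for i in range(n_flank):
                bins.append((g.end + flank - (i + 1) * flank_bin, g.end + flank - i * flank_bin))
            edges = np.linspace(g.end, g.start, n_body_bins + 1).astype(int)
            bins.extend((int(b), int(a)) for a, b in zip(edges[:-1], edges[1:]))
            for i in range(n_flank):
                bins.append((g.start - (i + 1) * flank_bin, g.start - i * flank_bin))
        for k, (s, e) in enumerate(bins):
            s = max(0, s)
            if e <= s:
                continue
            hit_counts[k] += count_in(g.chrom, s, e)
            bin_lengths[k] += e - s

    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(bin_lengths > 0, hit_counts / bin_lengths * 1e5, np.nan)
    return pd.DataFrame(
        {"bin": labels, "hits": hit_counts, "length": bin_lengths, "density_per_100kb": density}
    )


# --------------------------------------------------------------------------
# small RNA hosting
# --------------------------------------------------------------------------

def smallrna_hosts(
    small_rnas: ScoredTrack, transcripts: Annotation
) -> Tuple[pd.DataFrame, float]:
    """Assign small RNAs to host transcripts.

    A small RNA is hosted iff its interval lies fully inside some transcript's
    genomic span (introns included) on the same strand.
    """
    tx = list(transcripts.transcripts())
    by_cs: Dict[Tuple[str, str], List] = defaultdict(list)
    for t in tx:
        by_cs[(t.chrom, t.strand)].append(t)
    rows = []
    for iv in small_rnas:
        if iv.strand not in ("+", "-"):
            raise ValidationError(
                f"small RNA {iv.label or iv} lacks a strand"
            )
        hosts = [
            t.id
            for t in by_cs.get((iv.chrom, iv.strand), ())
            if t.start <= iv.start and iv.end <= t.end
        ]
        rows.append(
            {
                "small_rna": iv.label or f"{iv.chrom}:{iv.start}-{iv.end}",
                "hosted": bool(hosts),
                "hosts": ",".join(sorted(hosts)),
            }
        )
    df = pd.DataFrame(rows, columns=["small_rna", "hosted", "hosts"])
    fraction = float(df["hosted"].mean()) if len(df) else float("nan")
    return df, fraction


# --------------------------------------------------------------------------
# cross-set comparison
# --------------------------------------------------------------------------

def compare_sets(
    sets: Mapping[str, Annotation],
    tss_evidence: Sequence[ScoredTrack] = (),
    ccres: Sequence[CcreRecord] = (),
    peaks_by_tf: Optional[Mapping[str, ScoredTrack]] = None,
    gwas_hits: Optional[ScoredTrack] = None,
    genome: Optional[GenomeSequence] = None,
    window: int = 50,
) -> pd.DataFrame:
    """Side-by-side evidence support for several transcript sets.

    Runs each available characterization (evidence actually supplied) on each
    named set and tabulates fractions/densities, one row per set.
    """
    if len(sets) < 2:
        raise ValidationError("need at least two sets to compare")
    rows = []
    for name, ann in sets.items():
        tss = extract_tss(ann)
        row: Dict[str, object] = {"set": name, "n_transcripts": ann.n_transcripts(),
                                  "n_tss": len(tss)}
        if tss_evidence:
            s = tss_support(tss, tss_evidence, window=window)
            row["tss_support"] = s.fraction
            for track_name, frac in s.breakdown.items():
                row[f"tss_support_{track_name}"] = frac
        if ccres:
            s = ccre_support(tss, ccres)
            row["ccre_support_any"] = s.fraction
            for label in ("PLS", "pELS", "dELS"):
                if label in s.breakdown:
                    row[f"ccre_support_{label}"] = s.breakdown[label]
        if peaks_by_tf:
            profile, tf_counts = tf_coverage_profile(tss, peaks_by_tf)
            center = profile.loc[[-500, 0], "mean_coverage"].mean()
            row["tf_central_coverage"] = float(center)
            row["tf_mean_count_at_tss"] = float(tf_counts.mean())
        if gwas_hits is not None:
            row["gwas_density_gene_body"] = gwas_density(ann, gwas_hits, "gene_body")
            row["gwas_density_exons"] = gwas_density(ann, gwas_hits, "exons")
        if genome is not None:
            row["polya_support"] = polya_support(ann, genome).fraction
        rows.append(row)
    return pd.DataFrame(rows).set_index("set")
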