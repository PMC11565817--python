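"""Decoy transcript models: real structures relocated to intergenic space.

A decoy copies the exact exon/intron length sequence and strand of a
uniformly sampled source transcript and drops it at a uniformly sampled
position on the same chromosome.  Placements whose span comes within
``buffer`` bp of any annotated locus span are rejected and resampled, so the
decoy set mimics the transcript-structure statistics of the annotation while
being guaranteed non-genic.  All placement draws go through the integer
generator of ``numpy.random.default_rng`` so a fixed seed reproduces the set
bit-for-bit across platforms.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core import Annotation, TranscriptModel, ValidationError


@dataclass
class DecoyConfig:
    n_decoys: int = 1000
    seed: int = 0
    buffer: int = 1000
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.n_decoys < 1:
            raise ValidationError("n_decoys must be >= 1")
        if self.buffer < 0:
            raise ValidationError("buffer must be >= 0")


class PlacementError(RuntimeError):
    """No intergenic slot found for a structure within max_attempts."""


def _forbidden_index(
    annotation: Annotation, buffer: int
) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for g in annotation:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, g.start - buffer), g.end + buffer
        )
    return trees


def generate_decoys(
    annotation: Annotation,
    chrom_sizes: Mapping[str, int],
    config: DecoyConfig,
) -> Annotation:
    """Build ``config.n_decoys`` decoy transcripts, one gene per decoy.

    Each decoy records its source transcript id in ``tags['source_id']``.
    Decoys may overlap each other (background placements are independent);
    only overlap with the annotation is forbidden.
    """
    sources = sorted(annotation.transcripts(), key=lambda t: t.id)
    if not sources:
        raise ValidationError("annotation has no transcripts to relocate")
    for t in sources:
        if t.chrom not in chrom_sizes:
            raise ValidationError(f"no chromosome size for {t.chrom}")
    forbidden = _forbidden_index(annotation, config.buffer)
    rng = np.random.default_rng(config.seed)

    decoys: List[TranscriptModel] = []
    for i in range(config.n_decoys):
        src = sources[int(rng.integers(0, len(sources)))]
        span_len = src.end - src.start
        offsets = tuple((s - src.start, e - src.start) for s, e in src.exons)
        size = chrom_sizes[src.chrom]
        if size <= span_len:
            raise PlacementError(
                f"structure from {src.id} ({span_len} bp) exceeds {src.chrom}"
            )
        placed = None
        for _ in range(config.max_attempts):
            start = int(rng.integers(0, size - span_len))
            tree = forbidden.get(src.chrom)
            if tree is not None and tree.overlap(start, start + span_len):
                continue
            placed = start
            break
        if placed is None:
            raise PlacementError(
                f"could not place structure of source transcript {src.id} "
                f"({span_len} bp on {src.chrom}) after {config.max_attempts} attempts"
            )
        did = f"decoy_t{i + 1:05d}"
        decoys.append(
            TranscriptModel(
                id=did,
                chrom=src.chrom,
                strand=src.strand,
                exons=tuple((placed + s, placed + e) for s, e in offsets),
                gene_id=f"decoy_g{i + 1:05d}",
                biotype="decoy",
                tags={"source_id": src.id},
            )
        )
    return Annotation.from_transcripts(decoys)


def decoy_qc(
    decoys: Annotation, annotation: Annotation, buffer: int = 1000
) -> Dict[str, object]:
    """Audit a decoy set.

    Counts buffer-padded overlaps with the annotation (must be 0), and
    compares exon-count and exonic-length distributions between decoys and
    the annotation's transcripts with two-sample KS statistics (reported,
    not tested).
    """
    forbidden = _forbidden_index(annotation, buffer)
    violations = 0
    for t in decoys.transcripts():
        tree = forbidden.get(t.chrom)
        if tree is not None and tree.overlap(t.start, t.end):
            violations += 1

    d_counts = [len(t.exons) for t in decoys.transcripts()]
    d_lens = [t.exonic_length for t in decoys.transcripts()]
    s_counts = [len(t.exons) for t in annotation.transcripts()]
    s_lens = [t.exonic_length for t in annotation.transcripts()]
    ks_counts = stats.ks_2samp(d_counts, s_counts, method="asymp").statistic
    ks_lens = stats.ks_2samp(d_lens, s_lens, method="asymp").statistic

    # exact structure check against the actual sampled sources
    src_by_id = {t.id: t for t in annotation.transcripts()}
    structure_mismatches = 0
    for t in decoys.transcripts():
        src = src_by_id.get(t.tags.get("source_id", ""))
        if src is None:
            structure_mismatches += 1
            continue
        if tuple(e - s for s, e in t.exons) != tuple(e - s for s, e in src.exons):
            structure_mismatches += 1

    return {
        "n_decoys": decoys.n_transcripts(),
        "overlap_violations": violations,
        "structure_mismatches": structure_mismatches,
        "ks_exon_count": float(ks_counts),
        "ks_exonic_length": float(ks_lens),
        "exon_count_multiset": Counter(d_counts),
    }


def source_multiset(decoys: Annotation, annotation: Annotation) -> Tuple[Counter, Counter]:
    """(decoy multiset, source multiset) of (exon count, exonic length)."""
    src_by_id = {t.id: t for t in annotation.transcripts()}
    d = Counter((len(t.exons), t.exonic_length) for t in decoys.transcripts())
    s = Counter(
        (len(src_by_id[t.tags["source_id"]].exons),
         src_by_id[t.tags["source_id"]].exonic_length)
        for t in decoys.transcripts()
    )
    return d, s
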