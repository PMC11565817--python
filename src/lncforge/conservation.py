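"""Per-transcript conservation scoring against a per-base score track.

Scores (phyloP-style: positive = conserved, negative = accelerated) come in
as a bedGraph-backed :class:`ScoredTrack`.  A transcript's exon score is the
arithmetic mean over its exonic bases that the track covers; bases without
coverage are excluded from both numerator and denominator rather than imputed.
The junction score pools the first ``site_window`` intronic bases after each
donor and the last ``site_window`` before each acceptor — the window that
contains the canonical GT/AG dinucleotides at the default of 2 bp — so it
depends only on the intron chain, not on the termini.

Classification uses a neutral band (default -1.0 .. +1.0, boundaries
inclusive to neutral); the band can instead be calibrated empirically from
decoy-transcript scores, which approximate neutrally evolving sequence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Annotation, ScoredTrack, TranscriptModel, ValidationError


@dataclass(frozen=True)
class NeutralBand:
    lower: float = -1.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValidationError("neutral band requires lower < upper")


@dataclass
class ConservationScore:
    transcript_id: str
    exon_mean: Optional[float]
    junction_mean: Optional[float]
    n_exon_bases: int
    n_junction_bases: int


class _SegmentIndex:
    """Sorted non-overlapping (start, end, value) segments per chromosome."""

    def __init__(self, track: ScoredTrack):
        self.by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        grouped: Dict[str, List] = defaultdict(list)
        for iv in track:
            if iv.score is None:
                raise ValidationError("conservation track interval lacks a score")
            grouped[iv.chrom].append((iv.start, iv.end, float(iv.score)))
        for chrom, segs in grouped.items():
            segs.sort()
            for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"overlapping score segments on {chrom} at {s2}"
                    )
            self.by_chrom[chrom] = (
                np.array([s for s, _, _ in segs], dtype=np.int64),
                np.array([e for _, e, _ in segs], dtype=np.int64),
                np.array([v for _, _, v in segs], dtype=float),
            )

    def stats(self, chrom: str, intervals: Iterable[Tuple[int, int]]) -> Tuple[float, int]:
        """(sum of per-base scores, number of covered bases) over intervals."""
        got = self.by_chrom.get(chrom)
        if got is None:
            return 0.0, 0
        starts, ends, values = got
        total = 0.0
        n = 0
        for s, e in intervals:
            i = int(np.searchsorted(ends, s, side="right"))
            j = int(np.searchsorted(starts, e, side="left"))
            for k in range(i, j):
                ov = min(e, int(ends[k])) - max(s, int(starts[k]))
                if ov > 0:
                    total += values[k] * ov
                    n += ov
        return total, n


def _junction_windows(model: TranscriptModel, site_window: int) -> List[Tuple[int, int]]:
    out = []
    for donor, acceptor in model.introns:
        out.append((donor, min(donor + site_window, acceptor)))
        out.append((max(acceptor - site_window, donor), acceptor))
    return out


def transcript_exon_score(
    model: TranscriptModel, track: ScoredTrack, _index: Optional[_SegmentIndex] = None
) -> Optional[float]:
    """Mean per-base score over covered exonic positions; None when the track
    covers no exonic base."""
    idx = _index or _SegmentIndex(track)
    total, n = idx.stats(model.chrom, model.exons)
    return total / n if n else None


def transcript_junction_score(
    model: TranscriptModel,
    track: ScoredTrack,
    site_window: int = 2,
    _index: Optional[_SegmentIndex] = None,
) -> Optional[float]:
    """Mean per-base score over donor/acceptor windows pooled across the
    transcript's junctions; None for monoexonic models or uncovered sites."""
    if not model.is_spliced:
        return None
    idx = _index or _SegmentIndex(track)
    total, n = idx.stats(model.chrom, _junction_windows(model, site_window))
    return total / n if n else None


def score_annotation(
    annotation: Annotation, track: ScoredTrack, site_window: int = 2
) -> List[ConservationScore]:
    idx = _SegmentIndex(track)
    out = []
    for t in annotation.transcripts():
        e_total, e_n = idx.stats(t.chrom, t.exons)
        if t.is_spliced:
            j_total, j_n = idx.stats(t.chrom, _junction_windows(t, site_window))
        else:
            j_total, j_n = 0.0, 0
        out.append(
            ConservationScore(
                t.id,
                e_total / e_n if e_n else None,
                j_total / j_n if j_n else None,
                e_n,
                j_n,
            )
        )
    return out


def classify(score: Optional[float], band: NeutralBand = NeutralBand()) -> str:
    """conserved above the band, accelerated below, neutral inside (bounds
    inclusive to neutral); unclassified when no score is available."""
    if score is None:
        return "unclassified"
    if score > band.upper:
        return "conserved"
    if score < band.lower:
        return "accelerated"
    return "neutral"


def calibrate_band(
    decoy_scores: Sequence[float], central_mass: float = 0.95
) -> NeutralBand:
    """Empirical neutral band from decoy exon means: central quantiles
    ((1-mass)/2, 1-(1-mass)/2)."""
    scores = np.asarray([s for s in decoy_scores if s is not None], dtype=float)
    if len(scores) < 100:
        raise ValidationError(
            f"need >= 100 decoy scores to calibrate, got {len(scores)}"
        )
    if not (0 < central_mass <= 1):
        raise ValidationError("central_mass must lie in (0, 1]")
    alpha = (1 - central_mass) / 2
    lower = float(np.quantile(scores, alpha))
    upper = float(np.quantile(scores, 1 - alpha))
    if not lower < upper:
        raise ValidationError(
            "degenerate decoy score distribution: calibrated band is empty"
        )
    return NeutralBand(lower, upper)


def conservation_summary(
    sets: Mapping[str, Annotation],
    track: ScoredTrack,
    band: NeutralBand = NeutralBand(),
    site_window: int = 2,
    hist_bins: Optional[np.ndarray] = None,
) -> Tuple[pd.DataFrame, Dict[str, pd.DataFrame]]:
    """Per-set fractions of transcripts conserved/neutral/accelerated for exon
    and junction scores, plus histogram tables for plotting.

    Fractions are over classified (scored) transcripts.
    """
    if hist_bins is None:
        hist_bins = np.arange(-4.0, 6.01, 0.25)
    rows = []
    hists: Dict[str, pd.DataFrame] = {}
    for name, ann in sets.items():
        scores = score_annotation(ann, track, site_window)
        row: Dict[str, object] = {"set": name, "n_transcripts": len(scores)}
        for kind in ("exon", "junction"):
            vals = [
                getattr(s, f"{kind}_mean")
                for s in scores
                if getattr(s, f"{kind}_mean") is not None
            ]
            labels = [classify(v, band) for v in vals]
            n = len(labels)
            row[f"n_{kind}_scored"] = n
            for cat in ("conserved", "neutral", "accelerated"):
                row[f"{kind}_{cat}"] = (
                    labels.count(cat) / n if n else float("nan")
                )
            counts, edges = np.histogram(vals, bins=hist_bins)
            hists[f"{name}:{kind}"] = pd.DataFrame(
                {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("set"), hists
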