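"""Readers and writers for the external formats the pipeline touches.

Conventions handled here, and only here:

* GTF is 1-based inclusive; internal coordinates are 0-based half-open.
* UCSC chain files carry reversed-strand target coordinates when the target
  orientation is ``-``; they are stored verbatim in :class:`ChainAlignment`.
* BED/bedGraph are already 0-based half-open.

GTF attribute parsing accepts both the GENCODE dialect
(``key "value"; key "value";``) and bare ``key=value`` pairs; output is
always GENCODE dialect so written files are deterministic.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

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

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised on malformed input, naming the offending line."""


_ATTR_QUOTED = re.compile(r'(\w+)\s+"([^"]*)"')
_ATTR_EQ = re.compile(r"(\w+)=([^;]+)")


def _parse_attributes(field: str) -> Dict[str, str]:
    attrs = dict(_ATTR_QUOTED.findall(field))
    if not attrs:
        attrs = {k: v.strip().strip('"') for k, v in _ATTR_EQ.findall(field)}
    return attrs


# --------------------------------------------------------------------------
# GTF
# --------------------------------------------------------------------------

def read_gtf(path: PathLike) -> Annotation:
    """Read a GTF file into an :class:`Annotation`.

    Transcripts are assembled from ``exon`` features; ``gene``/``transcript``
    lines contribute biotype metadata when present.  Gene biotype falls back
    to ``other`` when no biotype attribute is given.
    """
    exons: Dict[str, List[Tuple[int, int]]] = {}
    tx_meta: Dict[str, Dict[str, str]] = {}
    gene_biotype: Dict[str, str] = {}
    tx_order: List[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates")
            if end1 < start1:
                raise ValidationError(f"{path}: line {lineno}: end < start")
            attrs = _parse_attributes(attr_s)
            biotype = attrs.get("gene_type") or attrs.get("gene_biotype")
            gid = attrs.get("gene_id")
            if biotype and gid:
                gene_biotype.setdefault(gid, biotype)
            if feature != "exon":
                continue
            tid = attrs.get("transcript_id")
            if not gid or not tid:
                raise ParseError(
                    f"{path}: line {lineno}: exon lacks gene_id/transcript_id"
                )
            if tid not in exons:
                exons[tid] = []
                tx_order.append(tid)
                tx_meta[tid] = {"gene_id": gid, "chrom": chrom, "strand": strand}
                for key in ("sample", "source_id"):
                    if key in attrs:
                        tx_meta[tid][f"tag:{key}"] = attrs[key]
            exons[tid].append((start1 - 1, end1))  # to 0-based half-open

    transcripts = []
    for tid in tx_order:
        meta = tx_meta[tid]
        gid = meta["gene_id"]
        tags = {k[4:]: v for k, v in meta.items() if k.startswith("tag:")}
        transcripts.append(
            TranscriptModel(
                id=tid,
                chrom=meta["chrom"],
                strand=meta["strand"],
                exons=tuple(sorted(exons[tid])),
                gene_id=gid,
                biotype=gene_biotype.get(gid, "other"),
                tags=tags,
            )
        )
    return Annotation.from_transcripts(transcripts)


def write_gtf(annotation: Annotation, path: PathLike) -> None:
    """Write GENCODE-dialect GTF with stable (chrom, start, gene, transcript)
    ordering; inverse of :func:`read_gtf` on valid annotations."""
    genes = sorted(
        annotation.genes.values(), key=lambda g: (g.chrom, g.start, g.id)
    )
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for g in genes:
            g_attrs = f'gene_id "{g.id}"; gene_type "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tlncforge\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{g_attrs}\n"
            )
            for t in sorted(g.transcripts, key=lambda t: (t.start, t.id)):
                t_attrs = (
                    f'gene_id "{g.id}"; transcript_id "{t.id}"; '
                    f'gene_type "{g.biotype}";'
                )
                for k in sorted(t.tags):
                    t_attrs += f' {k} "{t.tags[k]}";'
                fh.write(
                    f"{t.chrom}\tlncforge\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\t{t_attrs}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.chrom}\tlncforge\texon\t{s + 1}\t{e}\t.\t"
                        f"{t.strand}\t.\t{t_attrs}\n"
                    )


# --------------------------------------------------------------------------
# UCSC chain
# --------------------------------------------------------------------------

def read_chain(path: PathLike) -> List[ChainAlignment]:
    """Parse a UCSC chain file.

    Header layout: ``chain score tName tSize tStrand tStart tEnd qName qSize
    qStrand qStart qEnd id``.  The chain file's *target* (t) is our projection
    source and its *query* (q) our projection target, matching liftover usage.
    """
    chains: List[ChainAlignment] = []
    header: Optional[List[str]] = None
    blocks: List[Tuple[int, int, int]] = []
    s_pos = t_pos = 0

    def finish(lineno: int) -> None:
        nonlocal header, blocks
        if header is None:
            return
        (_, score, s_chrom, s_size, s_strand, s_start, s_end,
         t_chrom, t_size, t_strand, t_start, t_end) = header[:12]
        cid = header[12] if len(header) > 12 else str(len(chains) + 1)
        if s_strand != "+":
            raise ParseError(f"{path}: chain {cid}: source strand must be +")
        if s_pos != int(s_end) or t_pos != int(t_end):
            raise ParseError(
                f"{path}: chain {cid}: block sum mismatch with header span "
                f"(source ends at {s_pos}, header says {s_end}; "
                f"target ends at {t_pos}, header says {t_end})"
            )
        chains.append(
            ChainAlignment(
                s_chrom=s_chrom,
                s_size=int(s_size),
                t_chrom=t_chrom,
                t_size=int(t_size),
                t_orient=t_strand,
                blocks=blocks,
                chain_id=cid,
                score=float(score),
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish(lineno)
                header = line.split()
                if len(header) < 12:
                    raise ParseError(f"{path}: line {lineno}: short chain header")
                s_pos, t_pos = int(header[5]), int(header[10])
                blocks = []
                continue
            if header is None:
                raise ParseError(f"{path}: line {lineno}: block outside chain")
            parts = line.split()
            size = int(parts[0])
            blocks.append((s_pos, t_pos, size))
            if len(parts) == 3:
                s_pos += size + int(parts[1])
                t_pos += size + int(parts[2])
            elif len(parts) == 1:
                s_pos += size
                t_pos += size
            else:
                raise ParseError(f"{path}: line {lineno}: bad block line")
    finish(-1)
    return chains


def write_chain(chains: List[ChainAlignment], path: PathLike) -> None:
    with open(path, "w") as fh:
        for c in chains:
            first_s, first_t, _ = c.blocks[0]
            last_s, last_t, last_len = c.blocks[-1]
            fh.write(
                f"chain {int(c.score)} {c.s_chrom} {c.s_size} + "
                f"{first_s} {last_s + last_len} {c.t_chrom} {c.t_size} "
                f"{c.t_orient} {first_t} {last_t + last_len} {c.chain_id}\n"
            )
            for i, (ss, ts, ln) in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{ln}\n")
                else:
                    ns, nt, _ = c.blocks[i + 1]
                    fh.write(f"{ln} {ns - (ss + ln)} {nt - (ts + ln)}\n")
            fh.write("\n")


# --------------------------------------------------------------------------
# BED / bedGraph / FASTA / junction table
# --------------------------------------------------------------------------

def read_track(path: PathLike, kind: str = "bed", name: Optional[str] = None) -> ScoredTrack:
    """Read BED (3-6 columns) or bedGraph (4 columns) into a ScoredTrack."""
    if kind not in ("bed", "bedgraph"):
        raise ValueError(f"unknown track kind {kind!r}")
    track = ScoredTrack(name or Path(path).stem)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < (4 if kind == "bedgraph" else 3):
                raise ParseError(f"{path}: line {lineno}: too few columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if kind == "bedgraph":
                track.add(GenomicInterval(chrom, start, end, score=float(cols[3])))
                continue
            label = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score = (
                float(cols[4]) if len(cols) > 4 and cols[4] not in (".", "") else None
            )
            strand = cols[5] if len(cols) > 5 else "."
            track.add(GenomicInterval(chrom, start, end, strand, score, label))
    return track


def write_track(track: ScoredTrack, path: PathLike, kind: str = "bed") -> None:
    with open(path, "w") as fh:
        for iv in sorted(track.intervals, key=lambda x: x.sort_key):
            if kind == "bedgraph":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.score:g}\n")
            else:
                label = iv.label if iv.label is not None else "."
                score = f"{iv.score:g}" if iv.score is not None else "0"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t{score}\t{iv.strand}\n"
                )


def read_fasta(path: PathLike) -> GenomeSequence:
    return GenomeSequence(
        {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    )


def write_fasta(genome: GenomeSequence, path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sorted(genome.seqs.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_junction_support(path: PathLike) -> JunctionSupportTable:
    """Five-column TSV: chrom, strand, donor, acceptor, count."""
    table = JunctionSupportTable()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 columns")
            chrom, strand, donor, acceptor, count = cols
            c = int(count)
            if c < 0:
                raise ValidationError(
                    f"{path}: line {lineno}: negative junction count {c}"
                )
            table.set(SpliceJunction(chrom, strand, int(donor), int(acceptor)), c)
    return table


def write_junction_support(table: JunctionSupportTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstrand\tdonor\tacceptor\tcount\n")
        for j, c in sorted(
            table.items(), key=lambda kv: (kv[0].chrom, kv[0].donor, kv[0].acceptor, kv[0].strand)
        ):
            fh.write(f"{j.chrom}\t{j.strand}\t{j.donor}\t{j.acceptor}\t{c}\n")


def read_chrom_sizes(path: PathLike) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Dict[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def validate_file(path: PathLike) -> str:
    """Best-effort format validation used by ``lncforge validate``.

    Returns the detected format name; raises ParseError/ValidationError on
    malformed content.
    """
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix in (".gtf", ".gff"):
        read_gtf(p)
        return "gtf"
    if suffix == ".chain":
        read_chain(p)
        return "chain"
    if suffix in (".fa", ".fasta"):
        read_fasta(p)
        return "fasta"
    if suffix == ".bedgraph":
        read_track(p, "bedgraph")
        return "bedgraph"
    if suffix == ".bed":
        read_track(p, "bed")
        return "bed"
    if suffix in (".tsv", ".tab"):
        read_junction_support(p)
        return "junctions"
    raise ParseError(f"cannot infer format of {path}")
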