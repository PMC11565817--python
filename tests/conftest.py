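"""Shared fixtures: tiny hand-built annotations and a session-scoped
synthetic bundle so the expensive generation happens once."""

from __future__ import annotations

import numpy as np
import pytest

from lncforge.core import Annotation, GeneLocus, TranscriptModel
from lncforge.synthetic import SimConfig, simulate


def make_transcript(
    tid: str,
    exons,
    chrom: str = "chr1",
    strand: str = "+",
    gene_id=None,
    biotype: str = "lncRNA",
    tags=None,
) -> TranscriptModel:
    return TranscriptModel(
        id=tid,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        gene_id=gene_id or f"{tid}_g",
        biotype=biotype,
        tags=tags or {},
    )


def make_gene(gid, biotype, transcripts) -> GeneLocus:
    t = transcripts[0]
    return GeneLocus(gid, biotype, t.chrom, t.strand, list(transcripts))


def random_models(rng: np.random.Generator, n: int, n_chains: int = 40):
    """Random transcript models drawn from a limited pool of intron chains so
    that merging actually collapses some of them."""
    chains = []
    for _ in range(n_chains):
        chrom = f"chr{int(rng.integers(1, 3))}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        n_exons = int(rng.integers(1, 5))
        start = int(rng.integers(0, 100_000))
        exons = []
        pos = start
        for _ in range(n_exons):
            e = pos + int(rng.integers(50, 300))
            exons.append((pos, e))
            pos = e + int(rng.integers(100, 800))
        chains.append((chrom, strand, tuple(exons)))
    models = []
    for i in range(n):
        chrom, strand, exons = chains[int(rng.integers(0, len(chains)))]
        exons = list(exons)
        fs, fe = exons[0]
        exons[0] = (max(0, fs + int(rng.integers(-30, 30))), fe)
        ls, le = exons[-1]
        exons[-1] = (ls, le + int(rng.integers(-30, 30)))
        if exons[0][0] >= exons[0][1]:
            exons[0] = (exons[0][1] - 10, exons[0][1])
        if exons[-1][0] >= exons[-1][1]:
            exons[-1] = (exons[-1][0], exons[-1][0] + 10)
        models.append(
            make_transcript(f"m{i}", exons, chrom=chrom, strand=strand)
        )
    return models


@pytest.fixture(scope="session")
def bundle():
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=11)
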