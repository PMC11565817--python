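"""Chain projection against a per-base oracle, and reciprocal orthology."""

import numpy as np
import pytest

from lncforge.core import Annotation, ChainAlignment, GeneLocus, GenomicInterval
from lncforge.orthology import (
    OrthologyParams,
    candidate_orthologs,
    disease_ortholog_lookup,
    project_gene,
    project_interval,
    project_interval_per_base,
    reciprocal_orthology,
)

from conftest import make_gene, make_transcript


PLUS_CHAIN = ChainAlignment("chrA", 1000, "chrB", 5000, "+", [(100, 1100, 100)])


class TestProjectInterval:
    def test_offset_arithmetic_inside_block(self):
        res = project_interval(PLUS_CHAIN, GenomicInterval("chrA", 150, 160, "+"))
        assert [(f.start, f.end, f.strand) for f in res.fragments] == [(1150, 1160, "+")]
        assert res.mapped_fraction == 1.0

    def test_partial_overlap(self):
        res = project_interval(PLUS_CHAIN, GenomicInterval("chrA", 90, 110, "+"))
        assert [(f.start, f.end) for f in res.fragments] == [(1100, 1110)]
        assert res.mapped_fraction == pytest.approx(0.5)

    def test_off_chromosome_gives_empty_result(self):
        res = project_interval(PLUS_CHAIN, GenomicInterval("chrX", 150, 160, "+"))
        assert res.fragments == [] and res.mapped_fraction == 0.0

    def test_minus_chain_matches_per_base_oracle(self):
        chain = ChainAlignment("chrA", 1000, "chrB", 2000, "-", [(100, 300, 100)])
        iv = GenomicInterval("chrA", 100, 110, "+")
        res = project_interval(chain, iv)
        oracle = project_interval_per_base(chain, iv)
        bases = set()
        for f in res.fragments:
            assert f.strand == "-"
            bases.update(range(f.start, f.end))
        assert bases == {t for _, t, _ in oracle}
        assert all(s == "-" for _, _, s in oracle)

    @pytest.mark.parametrize("orient", ["+", "-"])
    def test_equals_oracle_on_random_multiblock_chains(self, orient):
        rng = np.random.default_rng(17)
        for trial in range(5):
            blocks = []
            s = t = int(rng.integers(0, 50))
            for _ in range(int(rng.integers(2, 8))):
                ln = int(rng.integers(5, 200))
                blocks.append((s, t, ln))
                s += ln + int(rng.integers(0, 100))
                t += ln + int(rng.integers(0, 100))
            chain = ChainAlignment("chrA", 10_000, "chrB", 10_000, orient, blocks)
            for start in range(0, blocks[-1][0] + blocks[-1][2] + 20, 7):
                for length in (1, 3, 10, 50, 200):
                    iv = GenomicInterval("chrA", start, start + length, "+")
                    res = project_interval(chain, iv)
                    got = set()
                    for f in res.fragments:
                        got.update((b, f.strand) for b in range(f.start, f.end))
                    want = {(t_, st) for _, t_, st in project_interval_per_base(chain, iv)}
                    assert got == want
                    assert res.mapped_bp == len(want)


class TestProjectGene:
    def test_full_coverage(self):
        g = make_gene("g", "lncRNA", [make_transcript("t", [(120, 140), (160, 180)], chrom="chrA")])
        proj = project_gene(g, [PLUS_CHAIN])
        assert proj.exons_mapped_fraction == 1.0
        assert proj.per_exon_fraction == [1.0, 1.0]

    def test_gene_in_chain_gap_projects_nothing(self):
        g = make_gene("g", "lncRNA", [make_transcript("t", [(500, 600)], chrom="chrA")])
        proj = project_gene(g, [PLUS_CHAIN])
        assert proj.fragments == [] and proj.exons_mapped_fraction == 0.0

    def test_best_scoring_chain_wins_per_exon(self):
        low = ChainAlignment("chrA", 1000, "chrB", 5000, "+", [(100, 2000, 100)],
                             chain_id="low", score=1.0)
        high = ChainAlignment("chrA", 1000, "chrB", 5000, "+", [(100, 3000, 100)],
                              chain_id="high", score=10.0)
        g = make_gene("g", "lncRNA", [make_transcript("t", [(120, 140)], chrom="chrA")])
        proj = project_gene(g, [low, high])
        assert proj.fragments[0].start == 3020


def _identity_chain(chrom, size):
    return ChainAlignment(chrom, size, chrom, size, "+", [(0, 0, size)], score=1.0)


class TestReciprocal:
    def test_identity_chain_self_orthology(self, bundle):
        lnc = bundle.lncrna_reference("a")
        chains = [
            _identity_chain(c, s) for c, s in bundle.chrom_sizes_a.items()
        ]
        calls = reciprocal_orthology(lnc, lnc, chains, chains)
        assert all(c.category == "one_to_one" for c in calls)
        assert all(c.gene_b == [c.gene_a] for c in calls)

    def test_wrong_strand_overlap_is_no_candidate(self):
        chain = _identity_chain("chr1", 10_000)
        a = make_gene("a", "lncRNA", [make_transcript("ta", [(100, 200)], strand="+")])
        b_ann = Annotation.from_transcripts(
            [make_transcript("tb", [(100, 200)], strand="-", gene_id="b")]
        )
        assert candidate_orthologs(a, b_ann, [chain]) == []

    def test_split_projection_threshold_rule(self):
        # projection lands 60/40 over two target genes; only the 60% passes 0.5
        chain = _identity_chain("chr1", 10_000)
        a = make_gene("a", "lncRNA", [make_transcript("ta", [(100, 200)])])
        b_ann = Annotation.from_transcripts(
            [
                make_transcript("b1", [(100, 160)], gene_id="g1"),
                make_transcript("b2", [(160, 200)], gene_id="g2"),
            ]
        )
        cands = candidate_orthologs(a, b_ann, [chain])
        assert [(g, round(f, 2)) for g, f in cands] == [("g1", 0.6)]

    def test_non_reciprocal_edge_dropped(self):
        """a1's best candidate is b1, but b1 reciprocates to a2 only: no edge."""
        chain = _identity_chain("chr1", 100_000)
        # b1 exon covers a2 fully and a1 partially; a1 projects fully onto b1,
        # but b1's projection overlaps a2's exon (a2 == b1's span) dominantly.
        a1 = make_transcript("a1", [(1000, 1100)], gene_id="a1")
        a2 = make_transcript("a2", [(2000, 3000)], gene_id="a2")
        b1 = make_transcript("b1", [(2000, 3000)], gene_id="b1")
        annot_a = Annotation.from_transcripts([a1, a2])
        annot_b = Annotation.from_transcripts([b1])
        calls = reciprocal_orthology(annot_a, annot_b, [chain], [chain])
        by_id = {c.gene_a: c for c in calls}
        assert by_id["a1"].category == "none"
        assert by_id["a2"].category == "one_to_one"

    def test_one_to_many_component(self):
        chain = _identity_chain("chr1", 100_000)
        a1 = make_transcript("a1", [(1000, 1500), (2000, 2500)], gene_id="a1")
        b1 = make_transcript("b1", [(1000, 1500)], gene_id="b1")
        b2 = make_transcript("b2", [(2000, 2500)], gene_id="b2")
        annot_a = Annotation.from_transcripts([a1])
        annot_b = Annotation.from_transcripts([b1, b2])
        calls = reciprocal_orthology(annot_a, annot_b, [chain], [chain])
        (call,) = calls
        assert call.category == "one_to_many"
        assert call.gene_b == ["b1", "b2"]

    def test_edge_relation_symmetric_on_simulation(self, bundle):
        lnc_a = bundle.lncrna_reference("a")
        lnc_b = bundle.lncrna_reference("b")
        ab = reciprocal_orthology(lnc_a, lnc_b, bundle.chains_ab, bundle.chains_ba)
        ba = reciprocal_orthology(lnc_b, lnc_a, bundle.chains_ba, bundle.chains_ab)
        edges_ab = {(c.gene_a, b) for c in ab for b in c.gene_b}
        edges_ba = {(b, c.gene_a) for c in ba for b in c.gene_b}
        assert edges_ab == edges_ba

    def test_planted_classes_recovered_exactly(self, bundle):
        calls = reciprocal_orthology(
            bundle.lncrna_reference("a"),
            bundle.lncrna_reference("b"),
            bundle.chains_ab,
            bundle.chains_ba,
        )
        truth = bundle.truth.ortholog_map
        by_id = {c.gene_a: c for c in calls}
        for gene_a, partners in truth.items():
            call = by_id[gene_a]
            assert sorted(call.gene_b) == sorted(partners)
            if not partners:
                assert call.category == "none"
            elif len(partners) == 1:
                assert call.category == "one_to_one"
            else:
                assert call.category == "one_to_many"

    def test_order_invariance(self, bundle):
        lnc_a = bundle.lncrna_reference("a")
        lnc_b = bundle.lncrna_reference("b")
        calls1 = reciprocal_orthology(lnc_a, lnc_b, bundle.chains_ab, bundle.chains_ba)
        shuffled_a = Annotation(list(lnc_a)[::-1])
        calls2 = reciprocal_orthology(shuffled_a, lnc_b, bundle.chains_ab, bundle.chains_ba)
        assert {(c.gene_a, tuple(c.gene_b), c.category) for c in calls1} == {
            (c.gene_a, tuple(c.gene_b), c.category) for c in calls2
        }


class TestDiseaseLookup:
    def test_fraction_with_ortholog(self, bundle):
        calls = reciprocal_orthology(
            bundle.lncrna_reference("a"),
            bundle.lncrna_reference("b"),
            bundle.chains_ab,
            bundle.chains_ba,
        )
        truth = bundle.truth.ortholog_map
        with_orth = [g for g, p in truth.items() if p]
        without = [g for g, p in truth.items() if not p]
        listed = with_orth[:1] + without[:3]
        df, summary = disease_ortholog_lookup(calls, listed)
        assert summary["fraction_with_ortholog"] == pytest.approx(0.25)
        assert len(df) == 4

    def test_empty_list_and_unmatched_ids(self, bundle):
        calls = []
        df, summary = disease_ortholog_lookup(calls, [])
        assert df.empty
        df2, s2 = disease_ortholog_lookup(calls, ["nope"])
        assert df2.iloc[0]["category"] == "not_in_annotation"
        assert s2["n_with_ortholog"] == 0
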