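"""Context precedence, nearby-gene assignment, QTL intersection and
hypergeometric enrichment against exact combinatorial oracles."""

import math

import numpy as np
import pytest

from cnvpop.annotation_overlap import (
    CONTEXT_CATEGORIES,
    classify_context,
    context_counts,
    enrich_terms,
    intersect_qtl,
)
from cnvpop.cnvr_builder import Cnvr
from cnvpop.io_formats import DataError, GeneModel, QtlRecord


def cnvr(start, end, cnvr_id="c1", chrom="chr1"):
    return Cnvr(cnvr_id, chrom, start, end, "gain", carriers={"s": {"DUP"}})


GENE = GeneModel("gA", "A", "chr1", 10_000, 20_000, "+", exons=[(10_000, 11_000), (18_000, 20_000)])


class TestContext:
    def test_precedence_exonic_over_everything(self):
        (ctx,) = classify_context([cnvr(10_200, 10_400)], [GENE])
        assert ctx.context == "exonic"

    def test_intron_only_overlap_is_intronic(self):
        (ctx,) = classify_context([cnvr(12_000, 13_000)], [GENE])
        assert ctx.context == "intronic"

    def test_upstream_downstream_are_strand_aware(self):
        minus = GeneModel("gB", "B", "chr1", 10_000, 20_000, "-")
        (up_plus,) = classify_context([cnvr(9_500, 9_900)], [GENE])
        (up_minus,) = classify_context([cnvr(20_100, 20_500)], [minus])
        (down_minus,) = classify_context([cnvr(9_500, 9_900)], [minus])
        assert up_plus.context == "upstream"
        assert up_minus.context == "upstream"
        assert down_minus.context == "downstream"

    def test_far_region_is_intergenic_and_empty_gene_set(self):
        (ctx,) = classify_context([cnvr(500_000, 501_000)], [GENE])
        assert ctx.context == "intergenic"
        assert ctx.genes_within_flank == set()

    def test_assignment_independent_of_precedence(self):
        # region covers an exon of gene A and the intron of adjacent gene B:
        # context is decided by the highest-precedence feature, assignment
        # collects both genes
        gene_b = GeneModel("gB", "B", "chr1", 20_500, 30_000, "+",
                           exons=[(29_000, 30_000)])
        (ctx,) = classify_context([cnvr(19_500, 21_000)], [GENE, gene_b])
        assert ctx.context == "exonic"
        assert ctx.genes_within_flank == {"gA", "gB"}

    def test_flank_window_controls_gene_assignment(self):
        (near,) = classify_context([cnvr(20_500, 21_000)], [GENE], flank=1000)
        (far,) = classify_context([cnvr(21_500, 22_000)], [GENE], flank=1000)
        assert near.genes_within_flank == {"gA"}
        assert far.genes_within_flank == set()

    def test_categories_partition_cohort(self, default_products):
        contexts = classify_context(default_products.cnvrs, default_products.cohort.genes)
        counts = context_counts(contexts)
        assert sum(counts.values()) == len(default_products.cnvrs)
        assert set(counts) == set(CONTEXT_CATEGORIES)


class TestQtl:
    QTLS = [
        QtlRecord("q1", "Body weight", "chr1", 0, 6_000_000),      # too wide
        QtlRecord("q2", "Tenderness score", "chr1", 5_000, 50_000),
        QtlRecord("q3", "Multiple birth", "chr1", 8_000, 40_000),
    ]

    def test_wide_qtl_removed_by_span_filter(self):
        pairs, summary = intersect_qtl([cnvr(1_000, 2_000)], self.QTLS)
        assert all(p.qtl_id != "q1" for p in pairs)

    def test_one_cnvr_in_two_qtls_counts_once_and_twice(self):
        pairs, summary = intersect_qtl([cnvr(10_000, 12_000)], self.QTLS)
        assert len(pairs) == 2
        assert summary.n_cnvrs_overlapping == 1
        assert summary.n_qtls_overlapped == 2

    def test_disjoint_sets_empty(self):
        pairs, summary = intersect_qtl([cnvr(100_000, 101_000)], self.QTLS)
        assert pairs == [] and summary.n_pairs == 0

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            cnvrs = [
                cnvr(int(s), int(s) + int(l), cnvr_id=f"c{i}")
                for i, (s, l) in enumerate(
                    zip(rng.integers(0, 900_000, 40), rng.integers(100, 30_000, 40))
                )
            ]
            qtls = [
                QtlRecord(f"q{i}", "t", "chr1", int(s), int(s) + int(l))
                for i, (s, l) in enumerate(
                    zip(rng.integers(0, 900_000, 40), rng.integers(1_000, 6_000_000, 40))
                )
            ]
            pairs, _ = intersect_qtl(cnvrs, qtls, max_qtl_span=5_000_000)
            got = {(p.cnvr_id, p.qtl_id, p.overlap_bp) for p in pairs}
            expected = set()
            for c in cnvrs:
                for q in qtls:
                    if q.span >= 5_000_000:
                        continue
                    ov = min(c.end, q.end) - max(c.start, q.start)
                    if ov > 0:
                        expected.add((c.cnvr_id, q.qtl_id, ov))
            assert got == expected


class TestEnrichment:
    def test_all_overlap_closed_form(self):
        # N=20 background, term covers K=5, query n=5 all in the term:
        # P(X >= 5) = 1 / C(20, 5)
        background = {f"g{i}" for i in range(20)}
        term_genes = {f"g{i}" for i in range(5)}
        (r,) = enrich_terms(term_genes, {"T": term_genes}, background)
        assert r.p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)
        assert r.k == r.K == r.n == 5 and r.N == 20

    def test_term_covering_whole_background_is_uninformative(self):
        background = {f"g{i}" for i in range(10)}
        (r,) = enrich_terms({"g0", "g1"}, {"T": set(background)}, background)
        assert r.p == pytest.approx(1.0)

    def test_matches_exhaustive_tail_sum_small_n(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            N = int(rng.integers(5, 31))
            background = {f"g{i}" for i in range(N)}
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            term_genes = set(rng.choice(sorted(background), size=K, replace=False))
            query = set(rng.choice(sorted(background), size=n, replace=False))
            k = len(term_genes & query)
            results = enrich_terms(query, {"T": term_genes}, background)
            if k == 0:
                assert results == []
                continue
            (r,) = results
            exact = sum(
                math.comb(K, j) * math.comb(N - K, n - j)
                for j in range(k, min(K, n) + 1)
            ) / math.comb(N, n)
            assert r.p == pytest.approx(exact, rel=1e-9)

    def test_identical_terms_get_identical_p_and_q(self):
        background = {f"g{i}" for i in range(12)}
        genes = {"g0", "g1", "g2"}
        term = {"g0", "g1", "g5"}
        r1, r2 = enrich_terms(genes, {"A": term, "B": set(term)}, background)
        assert r1.p == r2.p and r1.q == r2.q

    def test_bh_adjustment_is_monotone_and_bounded(self):
        rng = np.random.default_rng(37)
        background = {f"g{i}" for i in range(50)}
        query = set(rng.choice(sorted(background), 10, replace=False))
        term_map = {
            f"T{i}": set(rng.choice(sorted(background), int(rng.integers(3, 20)), replace=False))
            for i in range(8)
        }
        results = enrich_terms(query, term_map, background)
        for r in results:
            assert r.q >= r.p and r.q <= 1.0

    def test_input_validation(self):
        with pytest.raises(DataError, match="background"):
            enrich_terms({"a"}, {}, set())
        with pytest.raises(DataError, match="subset"):
            enrich_terms({"zz"}, {}, {"a", "b"})
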