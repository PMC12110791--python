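"""Genomic-context classification, QTL intersection and term enrichment.

Context follows a fixed precedence over the whole CNVR span: exonic if the
region touches any exon, else intronic if it touches any gene body, else
upstream/downstream if it lies within ``flank`` bp of a gene start/end on
the appropriate strand, else intergenic.  Gene *assignment* is independent
of the context label and strand-ignorant: every gene whose span inflated by
``flank`` bp intersects the CNVR is associated with it.

QTL overlap first removes catalogue entries whose genomic span is not
narrower than ``max_qtl_span`` (wide confidence intervals carry little
positional information), then reports every (CNVR, QTL) pair sharing at
least one base.

Enrichment is an explicit one-sided hypergeometric test per term with
Benjamini–Hochberg correction across the tested terms; both raw and
adjusted values are always reported so either can be thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .cnvr_builder import Cnvr
from .io_formats import DataError, GeneModel, QtlRecord

__all__ = [
    "ContextCall",
    "QtlOverlap",
    "QtlSummary",
    "EnrichmentResult",
    "CONTEXT_CATEGORIES",
    "classify_context",
    "context_counts",
    "intersect_qtl",
    "enrich_terms",
]

CONTEXT_CATEGORIES = ("exonic", "intronic", "upstream", "downstream", "intergenic")


@dataclass
class ContextCall:
    cnvr_id: str
    context: str
    genes_within_flank: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.context not in CONTEXT_CATEGORIES:
            raise ValueError(f"unknown context {self.context!r}")


@dataclass
class QtlOverlap:
    cnvr_id: str
    qtl_id: str
    trait_name: str
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("overlap_bp must be >= 1")


@dataclass
class QtlSummary:
    n_pairs: int
    n_cnvrs_overlapping: int
    n_qtls_overlapped: int
    per_trait_cnvr_counts: dict[str, int]


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # genes in set annotated with the term
    K: int  # background genes annotated with the term
    n: int  # gene-set size
    N: int  # background size
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("k cannot exceed min(K, n)")


def _add_interval(tree: IntervalTree, start: int, end: int, payload) -> None:
    if end > start:
        tree.addi(start, end, payload)


def classify_context(
    cnvrs: Sequence[Cnvr],
    genes: Sequence[GeneModel],
    flank: int = 1000,
) -> list[ContextCall]:
    """Assign one context category and the nearby-gene set to each CNVR."""
    exon_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    up_trees: dict[str, IntervalTree] = {}
    down_trees: dict[str, IntervalTree] = {}
    near_trees: dict[str, IntervalTree] = {}

    for g in genes:
        exon_t = exon_trees.setdefault(g.chrom, IntervalTree())
        for (s, e) in g.exons:
            _add_interval(exon_t, s, e, g.gene_id)
        _add_interval(body_trees.setdefault(g.chrom, IntervalTree()), g.start, g.end, g.gene_id)
        if g.strand == "+":
            up_s, up_e = max(0, g.start - flank), g.start
            down_s, down_e = g.end, g.end + flank
        else:
            up_s, up_e = g.end, g.end + flank
            down_s, down_e = max(0, g.start - flank), g.start
        _add_interval(up_trees.setdefault(g.chrom, IntervalTree()), up_s, up_e, g.gene_id)
        _add_interval(down_trees.setdefault(g.chrom, IntervalTree()), down_s, down_e, g.gene_id)
        _add_interval(
            near_trees.setdefault(g.chrom, IntervalTree()),
            max(0, g.start - flank),
            g.end + flank,
            g.gene_id,
        )

    out: list[ContextCall] = []
    for cnvr in cnvrs:
        s, e = cnvr.start, cnvr.end
        chrom = cnvr.chrom
        if exon_trees.get(chrom, IntervalTree()).overlap(s, e):
            context = "exonic"
        elif body_trees.get(chrom, IntervalTree()).overlap(s, e):
            context = "intronic"
        elif up_trees.get(chrom, IntervalTree()).overlap(s, e):
            context = "upstream"
        elif down_trees.get(chrom, IntervalTree()).overlap(s, e):
            context = "downstream"
        else:
            context = "intergenic"
        near = {iv.data for iv in near_trees.get(chrom, IntervalTree()).overlap(s, e)}
        out.append(ContextCall(cnvr_id=cnvr.cnvr_id, context=context, genes_within_flank=near))
    return out


def context_counts(contexts: Sequence[ContextCall]) -> dict[str, int]:
    counts = dict.fromkeys(CONTEXT_CATEGORIES, 0)
    for c in contexts:
        counts[c.context] += 1
    return counts


def intersect_qtl(
    cnvrs: Sequence[Cnvr],
    qtls: Sequence[QtlRecord],
    max_qtl_span: int = 5_000_000,
) -> tuple[list[QtlOverlap], QtlSummary]:
    """All CNVR x QTL overlaps after removing wide-span QTLs.

    A QTL is kept only when its span is strictly narrower than
    ``max_qtl_span``.  Every overlapping pair (>= 1 shared base) is
    reported; the summary counts distinct CNVRs, distinct QTLs, and
    distinct CNVRs per trait.
    """
    kept = [q for q in qtls if q.span < max_qtl_span]
    qtl_trees: dict[str, IntervalTree] = {}
    for q in kept:
        _add_interval(qtl_trees.setdefault(q.chrom, IntervalTree()), q.start, q.end, q)

    pairs: list[QtlOverlap] = []
    for cnvr in cnvrs:
        for iv in sorted(
            qtl_trees.get(cnvr.chrom, IntervalTree()).overlap(cnvr.start, cnvr.end),
            key=lambda iv: iv.data.qtl_id,
        ):
            q = iv.data
            ov = min(cnvr.end, q.end) - max(cnvr.start, q.start)
            pairs.append(
                QtlOverlap(
                    cnvr_id=cnvr.cnvr_id, qtl_id=q.qtl_id,
                    trait_name=q.trait_name, overlap_bp=ov,
                )
            )

    cnvr_set = {p.cnvr_id for p in pairs}
    qtl_set = {p.qtl_id for p in pairs}
    per_trait: dict[str, set[str]] = {}
    for p in pairs:
        per_trait.setdefault(p.trait_name, set()).add(p.cnvr_id)
    summary = QtlSummary(
        n_pairs=len(pairs),
        n_cnvrs_overlapping=len(cnvr_set),
        n_qtls_overlapped=len(qtl_set),
        per_trait_cnvr_counts={t: len(s) for t, s in sorted(per_trait.items())},
    )
    return pairs, summary


def enrich_terms(
    gene_set: Iterable[str],
    term_map: Mapping[str, tuple[str, set[str]]] | Mapping[str, set[str]],
    background: Iterable[str],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test per term.

    ``term_map`` maps term_id to either a gene set or a ``(term_name,
    gene_set)`` pair.  Term gene sets are intersected with the background;
    terms with no gene from the query set are skipped.  The upper-tail
    p-value P(X >= k) is computed per term and Benjamini–Hochberg adjusted
    across the tested terms; ``alpha`` is carried only as the conventional
    raw-p reporting threshold and does not remove rows.  Results are sorted
    by (p, term_id).
    """
    from statsmodels.stats.multitest import multipletests

    background = set(background)
    if not background:
        raise DataError("empty background gene set")
    gene_set = set(gene_set)
    if not gene_set <= background:
        raise DataError("gene_set must be a subset of the background")
    n = len(gene_set)
    N = len(background)

    rows: list[EnrichmentResult] = []
    for term_id in sorted(term_map):
        entry = term_map[term_id]
        if isinstance(entry, tuple):
            term_name, term_genes = entry
        else:
            term_name, term_genes = term_id, entry
        term_genes = set(term_genes) & background
        K = len(term_genes)
        k = len(term_genes & gene_set)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            EnrichmentResult(term_id=term_id, term_name=term_name, k=k, K=K, n=n, N=N,
                             p=min(p, 1.0), q=1.0)
        )
    if rows:
        _, qvals, _, _ = multipletests([r.p for r in rows], method="fdr_bh")
        for r, q in zip(rows, qvals):
            r.q = float(q)
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows
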