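"""Functional annotation of Methylation Peaks.

Each peak receives fractional scores over the categories promoter, exon,
intron and intergenic. A peak overlapping k distinct genic contexts gives
each context weight 1/k, so every peak carries total weight exactly 1
(computed in exact rational arithmetic). A context is a distinct
(category, strand, location) triple: two transcripts contributing the same
category at the same location count once. Intergenic (score 1) applies
only to peaks overlapping no genic context at all, and the intergenic
complement excludes promoters — a promoter base is genic.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneModel, GenomicInterval

CATEGORIES = ("promoter", "exon", "intron", "intergenic")
GENIC_CATEGORIES = ("promoter", "exon", "intron")


@dataclass
class PeakAnnotation:
    peak_id: str
    scores: dict[str, float]
    contexts: frozenset  # distinct (category, strand, start, end) triples hit


@dataclass
class IntergenicPartition:
    """Intergenic intervals per chromosome, flagged desert when strictly
    longer than the cutoff (default 500 kb)."""

    table: pd.DataFrame  # columns: chrom, start, end, desert(bool)
    desert_min_len: int

    def desert_length(self, chrom: str) -> int:
        sub = self.table[(self.table["chrom"] == chrom) & self.table["desert"]]
        return int((sub["end"] - sub["start"]).sum())

    def non_desert_length(self, chrom: str) -> int:
        sub = self.table[(self.table["chrom"] == chrom) & ~self.table["desert"]]
        return int((sub["end"] - sub["start"]).sum())


def promoter_interval(
    gene: GeneModel,
    up: int = 2000,
    down: int = 500,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Promoter: ``up`` bp upstream through ``down`` bp downstream of the
    TSS, strand-aware and clipped to chromosome bounds. On the + strand this
    is [tss-up, tss+down); on the - strand the mirror image
    [tss-down+1, tss+up+1)."""
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    elif gene.strand == "-":
        start, end = gene.tss - down + 1, gene.tss + up + 1
    else:
        raise ValueError(f"gene {gene.gene_id}: promoter needs a strand")
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def _gene_contexts(
    gene: GeneModel, up: int, down: int, chrom_length: int | None
) -> list[tuple[str, str, int, int]]:
    """(category, strand, start, end) context intervals of one gene:
    promoter, exons, and introns (gene body minus exons)."""
    ctx: list[tuple[str, str, int, int]] = []
    prom = promoter_interval(gene, up, down, chrom_length)
    ctx.append(("promoter", gene.strand, prom.start, prom.end))
    exons = sorted(gene.exons, key=lambda e: (e.start, e.end))
    for ex in exons:
        ctx.append(("exon", gene.strand, ex.start, ex.end))
    # introns: gaps between consecutive exons within the gene body
    merged: list[list[int]] = []
    for ex in exons:
        if merged and ex.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], ex.end)
        else:
            merged.append([ex.start, ex.end])
    for (s1, e1), (s2, _e2) in zip(merged, merged[1:]):
        if s2 > e1:
            ctx.append(("intron", gene.strand, e1, s2))
    return ctx


def build_context_index(
    genes: Sequence[GeneModel],
    up: int = 2000,
    down: int = 500,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for cat, strand, s, e in _gene_contexts(gene, up, down, clen):
            tree.addi(s, e, (cat, strand, s, e))
    return trees


def annotate_peaks(
    peaks: Sequence,
    genes: Sequence[GeneModel],
    up: int = 2000,
    down: int = 500,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[PeakAnnotation]:
    """Fractional category scores per peak under the 1/k rule.

    The result is independent of the gene input order: contexts are
    deduplicated as (category, strand, location) triples before weighting.
    """
    trees = build_context_index(genes, up, down, chrom_lengths)
    out: list[PeakAnnotation] = []
    for pk in peaks:
        tree = trees.get(pk.chrom)
        hits = frozenset(iv.data for iv in tree.overlap(pk.start, pk.end)) \
            if tree is not None else frozenset()
        scores = {cat: Fraction(0) for cat in CATEGORIES}
        if not hits:
            scores["intergenic"] = Fraction(1)
        else:
            w = Fraction(1, len(hits))
            for cat, _strand, _s, _e in hits:
                scores[cat] += w
        assert sum(scores.values()) == 1
        out.append(PeakAnnotation(
            pk.peak_id, {c: float(v) for c, v in scores.items()}, hits
        ))
    return out


def annotations_frame(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [[a.peak_id] + [a.scores.get(c, 0.0) for c in CATEGORIES]
         for a in annotations],
        columns=["peak_id", *CATEGORIES],
    ).set_index("peak_id")
    return frame


def category_distribution(annotations: Sequence[PeakAnnotation]) -> pd.Series:
    """Percentage of total fractional weight per category over all peaks."""
    frame = annotations_frame(annotations)
    totals = frame.sum(axis=0)
    return 100.0 * totals / totals.sum()


def partition_intergenic(
    chrom_lengths: Mapping[str, int],
    genes: Sequence[GeneModel],
    desert_min_len: int = 500_000,
    up: int = 2000,
    down: int = 500,
) -> IntergenicPartition:
    """Complement of (gene bodies plus promoters) per chromosome; intervals
    strictly longer than ``desert_min_len`` are labelled gene deserts."""
    covered: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for gene in genes:
        clen = chrom_lengths[gene.chrom]
        body = gene.span
        prom = promoter_interval(gene, up, down, clen)
        s = min(body.start, prom.start)
        e = min(max(body.end, prom.end), clen)
        covered[gene.chrom].append((s, e))
    rows = []
    for chrom, length in chrom_lengths.items():
        ivs = sorted(covered[chrom])
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cursor = 0
        for s, e in merged + [[length, length]]:
            if s > cursor:
                rows.append((chrom, cursor, s, (s - cursor) > desert_min_len))
            cursor = max(cursor, e)
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "desert"])
    return IntergenicPartition(table, desert_min_len)
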