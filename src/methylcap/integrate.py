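"""Integration: genes under putative promoter-methylation control.

A gene is "promoter-demethylated" when at least one significantly
down-methylated peak (log fold change < 0, q at or below the FDR level)
overlaps its promoter by any amount. Candidates are the intersection of
that set with the significantly upregulated genes; the
expression-independent promoter-demethylation list is emitted alongside.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import promoter_interval
from .io_formats import GeneModel


@dataclass
class CandidateGene:
    gene_id: str
    n_sig_promoter_peaks: int
    expr_logFC: float
    expr_q: float
    meth_peak_ids: tuple[str, ...]


def promoter_demethylated_genes(
    meth_results: pd.DataFrame,  # index peak_id; logFC, q, significant
    peaks: Sequence,             # MethylationPeak records
    genes: Sequence[GeneModel],
    fdr_q: float = 0.1,
    promoter_up: int = 2000,
    promoter_down: int = 500,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Genes whose promoter overlaps >= 1 significantly down-methylated peak.

    Returns gene_id-indexed frame with n_sig_promoter_peaks and the peak ids.
    """
    sig_down = meth_results[
        (meth_results["significant"]) & (meth_results["logFC"] < 0)
        & (meth_results["q"] <= fdr_q)
    ].index
    sig_set = set(sig_down)
    by_chrom: dict[str, list] = {}
    for pk in peaks:
        if pk.peak_id in sig_set:
            by_chrom.setdefault(pk.chrom, []).append(pk)
    for pks in by_chrom.values():
        pks.sort(key=lambda p: p.start)
    rows = []
    for gene in genes:
        pks = by_chrom.get(gene.chrom)
        if not pks:
            continue
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        prom = promoter_interval(gene, promoter_up, promoter_down, clen)
        hits = [pk.peak_id for pk in pks if pk.start < prom.end and prom.start < pk.end]
        if hits:
            rows.append((gene.gene_id, len(hits), ",".join(hits)))
    return pd.DataFrame(
        rows, columns=["gene_id", "n_sig_promoter_peaks", "meth_peak_ids"]
    ).set_index("gene_id")


def select_candidates(
    promoter_demeth: pd.DataFrame,
    expr_results: pd.DataFrame,  # index gene_id; logFC, q, significant
    fdr_q: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect promoter-demethylated genes with significantly upregulated
    genes. Returns (candidates, promoter-demethylation-only list). Genes
    with promoter demethylation but absent from the expression results are
    an error (id mismatch)."""
    unmatched = [g for g in promoter_demeth.index if g not in expr_results.index]
    if unmatched:
        raise ValueError(f"gene ids missing from expression results: {unmatched[:10]}")
    up = expr_results[
        (expr_results["significant"]) & (expr_results["logFC"] > 0)
        & (expr_results["q"] <= fdr_q)
    ]
    cand_ids = [g for g in promoter_demeth.index if g in set(up.index)]
    candidates = promoter_demeth.loc[cand_ids].copy()
    candidates["expr_logFC"] = expr_results.loc[cand_ids, "logFC"]
    candidates["expr_q"] = expr_results.loc[cand_ids, "q"]
    promoter_only = promoter_demeth.copy()
    promoter_only["expr_logFC"] = expr_results.loc[promoter_only.index, "logFC"]
    promoter_only["expr_q"] = expr_results.loc[promoter_only.index, "q"]
    return candidates, promoter_only


def percentage(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator, rounded to two decimals — every report
    percentage is exactly this function of the counts printed beside it."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * numerator / denominator, 2)


REQUIRED_STAGES = (
    "n_peaks", "n_significant_down_peaks", "n_genes",
    "n_promoter_demethylated_genes", "n_upregulated_genes",
    "n_downregulated_genes", "n_candidates",
)


def run_report(stage_counts: Mapping[str, int], config: Mapping | None = None,
               seed: int | None = None, extra: Mapping | None = None) -> dict:
    """Deterministic JSON-serialisable end-of-run summary with the stage
    counts and the percentages derived from them."""
    missing = [s for s in REQUIRED_STAGES if s not in stage_counts]
    if missing:
        raise ValueError(f"missing stage outputs: {missing}")
    c = dict(stage_counts)
    report = {
        "counts": c,
        "percentages": {
            "significant_down_peaks": percentage(
                c["n_significant_down_peaks"], c["n_peaks"]),
            "promoter_demethylated_genes": percentage(
                c["n_promoter_demethylated_genes"], c["n_genes"]),
            "candidates_of_upregulated": percentage(
                c["n_candidates"], c["n_upregulated_genes"]),
        },
        "config": dict(config) if config else {},
        "seed": seed,
    }
    if extra:
        report["extra"] = dict(extra)
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
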