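"""End-to-end pipeline on simulated or pre-loaded data.

Stages: RRBS summarisation and coverage filtering -> fragment
deduplication -> pooled control coverage -> threshold calibration against
RRBS -> peak calling -> per-peak fragment counting (and noise sizes) ->
paired NB differential methylation -> functional annotation ->
goodness-of-fit-normalised differential expression -> chromosome-matched
enrichment -> candidate-gene integration and run report.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotate import (annotate_peaks, annotations_frame, category_distribution,
                       partition_intergenic, promoter_interval)
from .differential import (DesignInfo, DispersionEstimate, bh_adjust,
                           estimate_common_dispersion, gof_normalize,
                           nb_paired_test, noise_offsets)
from .enrichment import DesertContrast, enrich, enrichment_frame, gene_desert_test
from .integrate import (promoter_demethylated_genes, run_report,
                        select_candidates)
from .io_formats import CountMatrix, FragmentSet, GeneModel, PipelineConfig
from .peaks import (CalibrationResult, CoverageTrack, MethylationPeak,
                    calibrate_threshold, call_peaks_genome,
                    count_fragments_per_peak, dedup_fragments, peaks_frame,
                    pile_coverage)
from .rrbs import concordance_report, filter_covered, summarize_cpg
from .simulate import (SimulatedStudy, SimulationParams, simulate_study,
                       truth_tables)


@dataclass
class PipelineResult:
    config: PipelineConfig
    calibration: CalibrationResult
    peaks: list[MethylationPeak]
    peak_counts: CountMatrix
    meth_results: pd.DataFrame
    meth_dispersion: DispersionEstimate
    expr_results: pd.DataFrame
    expr_dispersion: DispersionEstimate
    annotations: pd.DataFrame
    enrichment_genome: pd.DataFrame
    enrichment_genic: pd.DataFrame | None
    desert_contrast: DesertContrast | None
    candidates: pd.DataFrame
    promoter_demethylated: pd.DataFrame
    concordance: pd.DataFrame
    report: dict
    truth_eval: dict | None = None


def capture_coverage_at(
    tracks: Mapping[str, CoverageTrack], table: pd.DataFrame
) -> pd.DataFrame:
    """Pooled-control pileup value at each CpG position of ``table``
    (single-base lookup at the C of the dinucleotide)."""
    out = []
    for chrom, grp in table.groupby("chrom", sort=True):
        vals = tracks[chrom].values[grp["pos"].to_numpy()] if chrom in tracks \
            else np.zeros(len(grp), dtype=int)
        out.append(pd.DataFrame({
            "chrom": chrom, "pos": grp["pos"].to_numpy(), "capture_cov": vals,
        }))
    return pd.concat(out, ignore_index=True)


def peaks_in_genes(
    peaks: Sequence[MethylationPeak],
    genes: Sequence[GeneModel],
    gene_ids: set[str],
    config: PipelineConfig,
    chrom_lengths: Mapping[str, int],
) -> list[str]:
    """Peak ids overlapping the extent (promoter + body) of any listed gene."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.gene_id not in gene_ids:
            continue
        prom = promoter_interval(g, config.promoter_up, config.promoter_down,
                                 chrom_lengths.get(g.chrom))
        s = min(g.span.start, prom.start)
        e = max(g.span.end, prom.end)
        spans.setdefault(g.chrom, []).append((s, e))
    hits = []
    for pk in peaks:
        for s, e in spans.get(pk.chrom, ()):
            if pk.start < e and s < pk.end:
                hits.append(pk.peak_id)
                break
    return hits


def run_pipeline(
    study: SimulatedStudy | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    genome_kwargs: dict | None = None,
    methylome_kwargs: dict | None = None,
    sim_params: SimulationParams | None = None,
) -> PipelineResult:
    """Run the full analysis; simulates a study first when none is given."""
    config = config or PipelineConfig(seed=seed)
    if study is None:
        study = simulate_study(genome_kwargs, methylome_kwargs, sim_params, seed=seed)
    genome = study.genome
    chrom_lengths = genome.chrom_lengths

    # --- RRBS: per-CpG degrees, coverage filter
    rrbs_all = summarize_cpg(study.rrbs)
    rrbs_cov = filter_covered(rrbs_all, config.rrbs_min_cov)

    # --- capture: dedup, pooled control coverage
    dedup = {sid: dedup_fragments(fs) for sid, fs in study.capture.items()}
    controls = [dedup[s] for s in study.control_samples]
    tracks = {
        chrom: pile_coverage(controls, chrom, length)
        for chrom, length in chrom_lengths.items()
    }

    # --- calibration against RRBS, concordance QC
    cov_at_cpg = capture_coverage_at(tracks, rrbs_cov)
    merged = rrbs_cov.merge(cov_at_cpg, on=["chrom", "pos"])
    calibration = calibrate_threshold(
        merged["degree"].to_numpy(), merged["capture_cov"].to_numpy(),
        config.threshold_range,
    )
    concordance = concordance_report(rrbs_cov, cov_at_cpg)

    # --- peak calling and counting
    peaks = call_peaks_genome(tracks, calibration.chosen_t, genome.cpg_positions)
    peak_counts, _ = count_fragments_per_peak(dedup, peaks)

    # --- differential methylation (noise-size offsets)
    design_frame = study.design()
    offsets_meth = noise_offsets(dedup)
    design_meth = DesignInfo(
        samples=list(design_frame["sample"]),
        block=list(design_frame["block"]),
        treatment=list(design_frame["treatment"]),
        offsets=offsets_meth.loc[design_frame["sample"]].to_numpy(),
    )
    meth_disp = estimate_common_dispersion(peak_counts.counts[design_meth.samples],
                                           design_meth)
    meth_results = bh_adjust(
        nb_paired_test(peak_counts.counts[design_meth.samples], design_meth, meth_disp),
        config.fdr_q,
    )

    # --- annotation, intergenic partition, desert contrast
    annotations_list = annotate_peaks(
        peaks, genome.genes, config.promoter_up, config.promoter_down, chrom_lengths)
    annotations = annotations_frame(annotations_list)
    partition = partition_intergenic(
        chrom_lengths, genome.genes, config.desert_min_len,
        config.promoter_up, config.promoter_down)
    try:
        desert = gene_desert_test(peak_counts.counts, partition, peaks)
    except ValueError:
        desert = None

    # --- differential expression (GOF depth factors)
    expr_counts = study.rnaseq[design_meth.samples]
    factors = gof_normalize(expr_counts)
    col_totals = expr_counts.sum(axis=0)
    offsets_expr = np.log(
        factors.to_numpy() * col_totals.to_numpy() / col_totals.to_numpy().mean()
    )
    design_expr = DesignInfo(
        samples=design_meth.samples, block=design_meth.block,
        treatment=design_meth.treatment, offsets=offsets_expr,
    )
    expr_disp = estimate_common_dispersion(expr_counts, design_expr)
    expr_results = bh_adjust(
        nb_paired_test(expr_counts, design_expr, expr_disp), config.fdr_q)

    # --- enrichment
    sig_down = meth_results[
        meth_results["significant"] & (meth_results["logFC"] < 0)].index
    universe = peaks_frame(peaks)[["peak_id", "chrom"]]
    if len(sig_down):
        enr_genome = enrichment_frame(enrich(
            universe, list(sig_down), annotations,
            config.n_permutations, seed=config.seed, mode="genome_wide"))
    else:
        enr_genome = pd.DataFrame(
            columns=["category", "observed", "null_mean", "null_sd", "p", "direction"])
    up_genes = set(expr_results[
        expr_results["significant"] & (expr_results["logFC"] > 0)].index)
    genic_ids = set(peaks_in_genes(peaks, genome.genes, up_genes, config, chrom_lengths))
    sig_genic = [p for p in sig_down if p in genic_ids]
    enr_genic = None
    if sig_genic:
        uni_genic = universe[universe["peak_id"].isin(genic_ids)]
        enr_genic = enrichment_frame(enrich(
            uni_genic, sig_genic, annotations,
            config.n_permutations, seed=config.seed, mode="upregulated_genic"))

    # --- integration
    promoter_demeth = promoter_demethylated_genes(
        meth_results, peaks, genome.genes, config.fdr_q,
        config.promoter_up, config.promoter_down, chrom_lengths)
    candidates, promoter_only = select_candidates(
        promoter_demeth, expr_results, config.fdr_q)

    n_up = int((expr_results["significant"] & (expr_results["logFC"] > 0)).sum())
    n_down = int((expr_results["significant"] & (expr_results["logFC"] < 0)).sum())
    counts = {
        "n_peaks": len(peaks),
        "n_significant_down_peaks": int(len(sig_down)),
        "n_genes": len(genome.genes),
        "n_promoter_demethylated_genes": int(len(promoter_demeth)),
        "n_upregulated_genes": n_up,
        "n_downregulated_genes": n_down,
        "n_candidates": int(len(candidates)),
        "chosen_threshold": calibration.chosen_t,
    }

    truth_eval = None
    if study.methylome is not None:
        truth = set(study.methylome.regulated_genes)
        found = set(candidates.index)
        tp = len(truth & found)
        truth_eval = {
            "n_truth": len(truth),
            "n_called": len(found),
            "tp": tp,
            "sensitivity": tp / len(truth) if truth else float("nan"),
            "precision": tp / len(found) if found else float("nan"),
        }

    report = run_report(
        counts, config=config.asdict(), seed=seed,
        extra={
            "version": __version__,
            "category_distribution_pct":
                {k: round(float(v), 2)
                 for k, v in category_distribution(annotations_list).items()},
            **({"truth_eval": truth_eval} if truth_eval else {}),
        },
    )

    return PipelineResult(
        config=config, calibration=calibration, peaks=peaks,
        peak_counts=peak_counts, meth_results=meth_results,
        meth_dispersion=meth_disp, expr_results=expr_results,
        expr_dispersion=expr_disp, annotations=annotations,
        enrichment_genome=enr_genome, enrichment_genic=enr_genic,
        desert_contrast=desert, candidates=candidates,
        promoter_demethylated=promoter_only, concordance=concordance,
        report=report, truth_eval=truth_eval,
    )
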