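"""Chromosome-matched permutation enrichment and the gene-desert contrast.

The null distribution for category enrichment is built by repeatedly
drawing, for every chromosome, as many peaks (uniformly, without
replacement) from that chromosome's universe as there are significantly
down-methylated peaks on it — so the null respects the chromosomal layout
of the signal. Empirical two-sided p-values use the standard +1-corrected
estimator and therefore never return zero.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import CATEGORIES, GENIC_CATEGORIES, IntergenicPartition

MODES = ("genome_wide", "upregulated_genic")


@dataclass
class EnrichmentResult:
    category: str
    observed: float
    null_mean: float
    null_sd: float
    p_two_sided: float
    direction: str  # "enriched" | "depleted"


@dataclass
class DesertContrast:
    per_chrom: pd.DataFrame  # chrom, desert_density, non_desert_density
    t: float
    p: float
    zero_variance: bool = False
    n_straddlers: int = 0


def category_totals(
    peak_ids: Sequence[str], annotations: pd.DataFrame,
    categories: Sequence[str] = CATEGORIES,
) -> pd.Series:
    """Summed fractional scores per category over a peak set. Totals add up
    to the set size (each peak carries weight 1)."""
    missing = [p for p in peak_ids if p not in annotations.index]
    if missing:
        raise ValueError(f"unannotated peaks: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    sub = annotations.loc[list(peak_ids), list(categories)]
    return sub.sum(axis=0)


def resample_null(
    universe: pd.DataFrame,  # columns: peak_id, chrom
    significant_ids: Sequence[str],
    annotations: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
    categories: Sequence[str] = CATEGORIES,
) -> np.ndarray:
    """Null category-total distributions, (B, n_categories).

    Each iteration draws, per chromosome, the observed number of
    significant peaks on that chromosome uniformly without replacement
    from the universe restricted to that chromosome.
    """
    if n_permutations < 1:
        raise ValueError("need >=1 permutation iteration")
    sig = set(significant_ids)
    uni = universe.reset_index(drop=True)
    unknown = sig - set(uni["peak_id"])
    if unknown:
        raise ValueError(f"significant peaks outside universe: {sorted(unknown)[:5]}")
    scores = annotations.loc[uni["peak_id"], list(categories)].to_numpy()
    chrom_indices: list[np.ndarray] = []
    chrom_k: list[int] = []
    for chrom, grp in uni.groupby("chrom", sort=True):
        k = sum(1 for p in grp["peak_id"] if p in sig)
        if k == 0:
            continue
        if k > len(grp):
            raise ValueError(f"{chrom}: significant count exceeds universe")
        chrom_indices.append(grp.index.to_numpy())
        chrom_k.append(k)
    rng_children = np.random.SeedSequence([seed, 0x5EED]).spawn(n_permutations)
    null = np.empty((n_permutations, len(categories)))
    for b, child in enumerate(rng_children):
        rng = np.random.default_rng(child)
        total = np.zeros(len(categories))
        for idx, k in zip(chrom_indices, chrom_k):
            draw = rng.choice(idx, size=k, replace=False)
            assert len(draw) == k
            total += scores[draw].sum(axis=0)
        null[b] = total
    return null


def empirical_p(observed: float, null_scores: np.ndarray) -> tuple[float, str]:
    """+1-corrected two-sided empirical p and direction vs the null median."""
    null = np.asarray(null_scores, dtype=float)
    b = len(null)
    if b < 1:
        raise ValueError("need >=1 permutation iteration")
    p_hi = (np.sum(null >= observed) + 1) / (b + 1)
    p_lo = (np.sum(null <= observed) + 1) / (b + 1)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    direction = "enriched" if observed > np.median(null) else "depleted"
    return float(p), direction


def enrich(
    universe: pd.DataFrame,
    significant_ids: Sequence[str],
    annotations: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
    mode: str = "genome_wide",
) -> list[EnrichmentResult]:
    """Category enrichment of a significant peak set.

    genome_wide mode tests all four categories over the whole peak
    universe; upregulated_genic mode expects universe and significant set
    pre-filtered to peaks inside significantly upregulated genes and tests
    only the genic categories (no intergenic).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if len(universe) == 0:
        raise ValueError("empty peak universe")
    categories = CATEGORIES if mode == "genome_wide" else GENIC_CATEGORIES
    observed = category_totals(list(significant_ids), annotations, categories)
    null = resample_null(universe, significant_ids, annotations,
                         n_permutations, seed, categories)
    out = []
    for i, cat in enumerate(categories):
        p, direction = empirical_p(float(observed[cat]), null[:, i])
        out.append(EnrichmentResult(
            category=cat,
            observed=float(observed[cat]),
            null_mean=float(null[:, i].mean()),
            null_sd=float(null[:, i].std(ddof=1)) if len(null) > 1 else 0.0,
            p_two_sided=p,
            direction=direction,
        ))
    return out


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.category, r.observed, r.null_mean, r.null_sd, r.p_two_sided, r.direction)
         for r in results],
        columns=["category", "observed", "null_mean", "null_sd", "p", "direction"],
    )


def gene_desert_test(
    peak_counts: pd.DataFrame,      # peaks x samples fragment counts
    partition: IntergenicPartition,
    peaks: Sequence,                # MethylationPeak records
    pooled: bool = True,
) -> DesertContrast:
    """Length-normalised peak-read density in gene deserts vs other
    intergenic regions, compared per chromosome by a paired t-test.

    A peak contributes its fragment counts to a group when it overlaps any
    intergenic interval of that group (a rare straddler contributes to
    both; the count of such peaks is reported). Only chromosomes with at
    least one desert enter the test.
    """
    tab = partition.table
    rows = []
    straddlers = 0
    chroms_with_desert = sorted(tab.loc[tab["desert"], "chrom"].unique())
    if len(chroms_with_desert) < 2:
        raise ValueError("need >=2 chromosomes with gene deserts")
    for chrom in chroms_with_desert:
        sub = tab[tab["chrom"] == chrom]
        desert_iv = sub[sub["desert"]][["start", "end"]].to_numpy()
        other_iv = sub[~sub["desert"]][["start", "end"]].to_numpy()
        d_len = int((desert_iv[:, 1] - desert_iv[:, 0]).sum())
        o_len = int((other_iv[:, 1] - other_iv[:, 0]).sum())
        d_count = o_count = 0
        for pk in peaks:
            if pk.chrom != chrom:
                continue
            in_desert = any(pk.start < e and s < pk.end for s, e in desert_iv)
            in_other = any(pk.start < e and s < pk.end for s, e in other_iv)
            if not (in_desert or in_other):
                continue
            if in_desert and in_other:
                straddlers += 1
            total = int(peak_counts.loc[pk.peak_id].sum()) if pooled else \
                int(peak_counts.loc[pk.peak_id].iloc[0])
            if in_desert:
                d_count += total
            if in_other:
                o_count += total
        rows.append({
            "chrom": chrom,
            "desert_density": d_count / d_len if d_len else np.nan,
            "non_desert_density": o_count / o_len if o_len else np.nan,
        })
    per_chrom = pd.DataFrame(rows).dropna()
    if len(per_chrom) < 2:
        raise ValueError("need >=2 chromosomes with both desert and non-desert lengths")
    diffs = per_chrom["desert_density"] - per_chrom["non_desert_density"]
    if np.allclose(diffs.std(ddof=1), 0.0):
        t = 0.0 if np.allclose(diffs, 0.0) else np.nan
        return DesertContrast(per_chrom, t=t, p=np.nan if not np.allclose(diffs, 0) else 1.0,
                              zero_variance=True, n_straddlers=straddlers)
    t, p = stats.ttest_rel(per_chrom["desert_density"], per_chrom["non_desert_density"])
    return DesertContrast(per_chrom, t=float(t), p=float(p), n_straddlers=straddlers)
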