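"""Synthetic genomes, methylomes and sequencing data with known truth.

The simulator emulates the study design the pipeline is built for: two
cell lines, each profiled untreated/solvent (control) and after a
demethylating-agent treatment, on a toy genome with CpG-dense promoters.
Per-CpG methylation degrees follow a bimodal (low/high) mixture; capture
fragment intensity grows with the summed methylation of nearby CpGs, so
the capture-coverage/bisulfite-degree concordance emerges from the model
rather than being hard-coded; bisulfite counts are binomial at
negative-binomially distributed coverage; and RNA-seq means decrease
exponentially with mean promoter methylation.

Ground truth (which genes were demethylated, per-condition degrees) is
carried alongside every data set so downstream calls can be scored.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FragmentSet, GeneModel, GenomicInterval

CELL_LINES = ("L1", "L2")
TREATMENTS = ("control", "treated")
CONDITIONS = tuple((cl, tr) for cl in CELL_LINES for tr in TREATMENTS)

_FRAG_LEN_MIN, _FRAG_LEN_MAX = 50, 400


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive an independent generator for a named pipeline stage.

    The stage name is hashed (CRC-32) and combined with the user seed in a
    SeedSequence, so each stage gets a reproducible, independent stream and
    re-running one stage never perturbs another.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


@dataclass
class ToyGenome:
    chrom_lengths: dict[str, int]
    cpg_positions: dict[str, np.ndarray]  # sorted CpG start positions
    genes: list[GeneModel]
    desert_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, pos in self.cpg_positions.items():
            length = self.chrom_lengths[chrom]
            if len(pos) and (np.diff(pos) <= 0).any():
                raise ValueError(f"{chrom}: CpG positions not strictly increasing")
            if len(pos) and (pos[-1] > length - 2 or pos[0] < 0):
                raise ValueError(f"{chrom}: CpG position out of bounds")
        for gene in self.genes:
            if gene.span.end > self.chrom_lengths[gene.chrom]:
                raise ValueError(f"gene {gene.gene_id} exceeds chromosome bounds")

    @property
    def n_cpg(self) -> int:
        return sum(len(p) for p in self.cpg_positions.values())

    def genes_by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {c: [] for c in self.chrom_lengths}
        for g in self.genes:
            out[g.chrom].append(g)
        for gl in out.values():
            gl.sort(key=lambda g: g.span.start)
        return out


@dataclass
class MethylomeTruth:
    """Per-condition methylation degrees plus the planted treatment effect."""

    # (cell_line, treatment) -> chrom -> degree array aligned with cpg_positions
    degrees: dict[tuple[str, str], dict[str, np.ndarray]]
    regulated_genes: frozenset[str]
    affected: dict[str, np.ndarray]  # chrom -> boolean mask over CpGs
    delta: float

    def condition(self, cell_line: str, treatment: str) -> dict[str, np.ndarray]:
        return self.degrees[(cell_line, treatment)]


@dataclass
class SimulationParams:
    """Sequencing-simulation knobs.

    capture_depth is the expected fragment count per capture library;
    fragment lengths are truncated-normal around 200 bp as in a sheared
    library sized for ~200 bp inserts. rrbs_mean_cov defaults to deep
    (123x) coverage; rrbs_covered_fraction to ~11% of genomic CpGs.
    desert_intensity_factor scales capture intensity inside gene deserts
    (1 = no special behaviour).
    """

    capture_depth: int = 50_000
    frag_len_mean: float = 200.0
    frag_len_sd: float = 60.0
    capture_noise_floor: float = 0.05
    dup_rate: float = 0.10
    rrbs_mean_cov: float = 123.0
    rrbs_covered_fraction: float = 0.11
    rrbs_nb_size: float = 5.0
    rnaseq_depth: float = 300_000.0
    expr_beta: float = 2.0
    nb_dispersion: float = 0.05
    desert_intensity_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.frag_len_mean <= 0:
            raise ValueError("frag_len_mean must be positive")
        if not (0 <= self.dup_rate < 1):
            raise ValueError("dup_rate must be in [0,1)")
        for name in ("capture_depth", "frag_len_sd", "capture_noise_floor",
                     "rrbs_mean_cov", "rrbs_covered_fraction", "rnaseq_depth",
                     "expr_beta", "nb_dispersion", "desert_intensity_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# genome


def _place_genes(
    rng: np.random.Generator,
    chrom_len: int,
    n_genes: int,
    forbidden: tuple[int, int] | None,
    promoter_span: int = 2_501,
) -> list[tuple[int, int, str]]:
    """Walk the chromosome left to right, placing non-overlapping gene bodies
    with room for a promoter upstream of each. Returns (start, end, strand)."""
    placements: list[tuple[int, int, str]] = []
    pos = promoter_span + 500
    for _ in range(n_genes):
        # gaps wide enough that neighbouring promoter windows (2 kb up /
        # 0.5 kb down of the TSS, either orientation) never overlap
        gap = int(rng.integers(4_600, 5_400))
        length = int(rng.integers(2_000, 5_001))
        start = pos + gap
        if forbidden is not None and start + length + promoter_span > forbidden[0] \
                and start < forbidden[1] + promoter_span:
            start = forbidden[1] + promoter_span + gap
        end = start + length
        if end + promoter_span > chrom_len:
            raise ValueError(
                f"cannot fit {n_genes} genes in a {chrom_len} bp chromosome"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        placements.append((start, end, strand))
        pos = end
    return placements


def _make_exons(
    rng: np.random.Generator, chrom: str, start: int, end: int, strand: str
) -> list[GenomicInterval]:
    n_exon = int(rng.integers(1, 6))
    cuts = np.sort(rng.choice(np.arange(start + 100, end - 100), size=2 * n_exon - 2,
                              replace=False)) if n_exon > 1 else np.array([], dtype=int)
    bounds = np.concatenate([[start], cuts, [end]])
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        s, e = int(bounds[i]), int(bounds[i + 1])
        if e > s:
            exons.append(GenomicInterval(chrom, s, e, strand))
    if not exons:  # degenerate cut layout; fall back to single exon
        exons = [GenomicInterval(chrom, start, end, strand)]
    return exons


def promoter_window(gene: GeneModel, up: int = 2000, down: int = 500) -> tuple[int, int]:
    """Strand-aware promoter span [tss-up, tss+down) on +, mirrored on -."""
    if gene.strand == "+":
        return max(0, gene.tss - up), gene.tss + down
    return max(0, gene.tss - down + 1), gene.tss + up + 1


def generate_genome(
    n_chrom: int = 2,
    chrom_len: int = 2_000_000,
    n_genes: int = 300,
    island_density: float = 0.04,
    background_density: float = 0.004,
    desert_chroms: Sequence[str] = ("chr1", "chr2"),
    seed: int = 0,
    desert_min_len: int = 500_000,
) -> ToyGenome:
    """Generate a toy genome: non-overlapping genes, CpG starts drawn from a
    two-rate Bernoulli process (high rate in promoter windows, low elsewhere),
    and one intergenic desert block longer than ``desert_min_len`` on each
    requested chromosome.
    """
    if not (0 < island_density < 1 and 0 < background_density < 1):
        raise ValueError("densities must be in (0,1)")
    rng = stage_rng(seed, "genome")
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    chrom_lengths = {c: int(chrom_len) for c in chrom_names}
    per_chrom = np.full(n_chrom, n_genes // n_chrom)
    per_chrom[: n_genes % n_chrom] += 1

    genes: list[GeneModel] = []
    desert_intervals: dict[str, tuple[int, int]] = {}
    gene_no = 0
    for chrom, n_c in zip(chrom_names, per_chrom):
        forbidden = None
        if chrom in desert_chroms:
            d_len = int(desert_min_len * 1.2)
            d_start = int(rng.integers(chrom_len // 4, chrom_len - d_len - 10_000))
            forbidden = (d_start, d_start + d_len)
            desert_intervals[chrom] = forbidden
        for start, end, strand in _place_genes(rng, chrom_len, int(n_c), forbidden):
            gene_no += 1
            exons = _make_exons(rng, chrom, start, end, strand)
            genes.append(GeneModel.from_exons(f"gene_{gene_no}", chrom, strand, exons))

    by_chrom = {c: [] for c in chrom_names}
    for g in genes:
        by_chrom[g.chrom].append(g)

    cpg_positions: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        rate = np.full(chrom_len, background_density)
        for g in by_chrom[chrom]:
            s, e = promoter_window(g)
            rate[s:min(e, chrom_len)] = island_density
        hits = np.flatnonzero(rng.random(chrom_len) < rate)
        hits = hits[hits <= chrom_len - 2]
        # enforce non-overlapping dinucleotides (spacing >= 2)
        if len(hits) > 1:
            keep = [0]
            for i in range(1, len(hits)):
                if hits[i] - hits[keep[-1]] >= 2:
                    keep.append(i)
            hits = hits[keep]
        cpg_positions[chrom] = hits.astype(np.int64)

    genome = ToyGenome(chrom_lengths, cpg_positions, genes, desert_intervals)
    for chrom in desert_chroms:
        if chrom in chrom_lengths:
            d = desert_intervals[chrom]
            if d[1] - d[0] <= desert_min_len:
                raise AssertionError("requested desert shorter than minimum")
    return genome


# ---------------------------------------------------------------------------
# methylome

BaselineMix = tuple[float, object, object]  # (weight_low, low_comp, high_comp)

DEFAULT_BASELINE_MIX: BaselineMix = (0.35, (1.5, 15.0), (15.0, 1.5))


def _draw_component(rng: np.random.Generator, comp, size: int) -> np.ndarray:
    """A mixture component is either (a, b) Beta parameters or a scalar
    point mass."""
    if np.isscalar(comp):
        return np.full(size, float(comp))
    a, b = comp
    return rng.beta(a, b, size=size)


def generate_methylome(
    genome: ToyGenome,
    baseline_mix: BaselineMix = DEFAULT_BASELINE_MIX,
    n_regulated: int = 50,
    delta: float = 0.25,
    cellline_sd: float = 0.2,
    seed: int = 0,
) -> MethylomeTruth:
    """Plant a demethylation effect: ``n_regulated`` genes get uniformly
    high-methylated promoter CpGs at baseline, and under treatment those
    CpGs' degrees are multiplied by ``delta``. All other CpGs are identical
    between control and treated. A small per-cell-line logit perturbation is
    applied symmetrically across the two conditions of each cell line.
    """
    if not (0 < delta <= 1):
        raise ValueError("delta must be in (0,1]")
    if n_regulated > len(genome.genes):
        raise ValueError("n_regulated exceeds number of genes")
    w_low, low_comp, high_comp = baseline_mix
    rng = stage_rng(seed, "methylome")

    regulated = frozenset(
        g.gene_id
        for g in rng.choice(np.asarray(genome.genes, dtype=object),
                            size=n_regulated, replace=False)
    ) if n_regulated else frozenset()

    baseline: dict[str, np.ndarray] = {}
    affected: dict[str, np.ndarray] = {}
    by_chrom = genome.genes_by_chrom()
    for chrom, cpgs in genome.cpg_positions.items():
        n = len(cpgs)
        # background CpGs: independent low/high mixture draws
        is_low = rng.random(n) < w_low
        deg = np.where(
            is_low,
            _draw_component(rng, low_comp, n),
            _draw_component(rng, high_comp, n),
        )
        mask = np.zeros(n, dtype=bool)
        for g in by_chrom.get(chrom, []):
            s, e = promoter_window(g)
            lo, hi = np.searchsorted(cpgs, [s, e])
            if hi <= lo:
                continue
            if g.gene_id in regulated:
                # planted signal: coherently high-methylated promoter island
                deg[lo:hi] = _draw_component(rng, high_comp, hi - lo)
                mask[lo:hi] = True
            else:
                # methylation is regionally correlated: one island-level
                # state shared by all CpGs of a promoter island
                comp = low_comp if rng.random() < w_low else high_comp
                deg[lo:hi] = _draw_component(rng, comp, hi - lo)
        baseline[chrom] = np.clip(deg, 0.0, 1.0)
        affected[chrom] = mask

    degrees: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for cell_line in CELL_LINES:
        shift = {
            chrom: rng.normal(0.0, cellline_sd, size=len(cpgs))
            for chrom, cpgs in genome.cpg_positions.items()
        } if cellline_sd > 0 else None
        for treatment in TREATMENTS:
            cond: dict[str, np.ndarray] = {}
            for chrom, base in baseline.items():
                deg = base.copy()
                if treatment == "treated":
                    deg[affected[chrom]] *= delta
                if shift is not None:
                    # logit-scale shift, identical across the two treatments
                    eps = 1e-6
                    d = np.clip(deg, eps, 1 - eps)
                    deg = np.where(
                        (deg <= 0) | (deg >= 1),
                        deg,
                        1.0 / (1.0 + np.exp(-(np.log(d / (1 - d)) + shift[chrom]))),
                    )
                cond[chrom] = np.clip(deg, 0.0, 1.0)
            degrees[(cell_line, treatment)] = cond
    return MethylomeTruth(degrees, regulated, affected, delta)


# ---------------------------------------------------------------------------
# MethylCap fragments


def _capture_intensity(
    genome: ToyGenome,
    cond_degrees: Mapping[str, np.ndarray],
    params: SimulationParams,
    chrom: str,
) -> np.ndarray:
    """Per-base fragment-start intensity: noise floor plus the window sum of
    CpG methylation degrees over one mean fragment length, mimicking MBD
    affinity increasing with local methyl-CpG content."""
    length = genome.chrom_lengths[chrom]
    point = np.zeros(length)
    cpgs = genome.cpg_positions[chrom]
    np.add.at(point, cpgs, cond_degrees[chrom])
    w = max(1, int(round(params.frag_len_mean)))
    # centred moving window sum via cumulative sums
    cs = np.concatenate([[0.0], np.cumsum(point)])
    lo = np.clip(np.arange(length) - w // 2, 0, length)
    hi = np.clip(np.arange(length) + (w - w // 2), 0, length)
    intensity = params.capture_noise_floor + (cs[hi] - cs[lo])
    if params.desert_intensity_factor != 1.0 and chrom in genome.desert_intervals:
        s, e = genome.desert_intervals[chrom]
        intensity[s:e] *= params.desert_intensity_factor
    return intensity


def simulate_methylcap(
    genome: ToyGenome,
    methylome: MethylomeTruth,
    params: SimulationParams,
    condition: tuple[str, str],
    seed: int = 0,
) -> FragmentSet:
    """Emit one capture library: fragment starts are drawn proportional to
    the methylation-weighted intensity, lengths are truncated-normal in
    [50, 400] bp, and ``dup_rate`` of emitted fragments are exact copies of
    earlier ones (PCR duplicates).
    """
    cell_line, treatment = condition
    rng = stage_rng(seed, f"methylcap:{cell_line}:{treatment}")
    sample_id = f"{cell_line}_{treatment}"
    n_total = int(rng.poisson(params.capture_depth))
    if n_total == 0:
        return FragmentSet(sample_id, pd.DataFrame(columns=["chrom", "start", "end"]))
    n_dup = int(round(params.dup_rate * n_total))
    n_orig = n_total - n_dup

    cond = methylome.condition(cell_line, treatment)
    chroms = list(genome.chrom_lengths)
    intensities = {c: _capture_intensity(genome, cond, params, c) for c in chroms}
    masses = np.array([intensities[c].sum() for c in chroms])
    if masses.sum() <= 0:
        raise ValueError("zero total capture intensity")
    n_per_chrom = rng.multinomial(n_orig, masses / masses.sum())

    frames = []
    for chrom, n_c in zip(chroms, n_per_chrom):
        if n_c == 0:
            continue
        length = genome.chrom_lengths[chrom]
        cum = np.cumsum(intensities[chrom])
        starts = np.searchsorted(cum, rng.random(n_c) * cum[-1], side="right")
        a = (_FRAG_LEN_MIN - params.frag_len_mean) / params.frag_len_sd
        b = (_FRAG_LEN_MAX - params.frag_len_mean) / params.frag_len_sd
        lens = stats.truncnorm.rvs(
            a, b, loc=params.frag_len_mean, scale=params.frag_len_sd,
            size=n_c, random_state=rng,
        ).round().astype(np.int64)
        starts = np.minimum(starts, length - _FRAG_LEN_MIN).astype(np.int64)
        ends = np.minimum(starts + lens, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    frame = pd.concat(frames, ignore_index=True)
    if n_dup > 0 and len(frame) > 0:
        dup_idx = rng.integers(0, len(frame), size=n_dup)
        frame = pd.concat([frame, frame.iloc[dup_idx]], ignore_index=True)
    frame = frame.sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(0, 2**31 - 1))).reset_index(drop=True)
    return FragmentSet(sample_id, frame)


# ---------------------------------------------------------------------------
# RRBS


def simulate_rrbs(
    methylome: MethylomeTruth,
    genome: ToyGenome,
    rrbs_mean_cov: float = 123.0,
    covered_fraction: float = 0.11,
    condition: tuple[str, str] = ("L1", "control"),
    seed: int = 0,
    nb_size: float = 5.0,
) -> pd.DataFrame:
    """Bisulfite counts at a random subset of CpGs: coverage is
    negative-binomial with the given mean, methylated counts are
    binomial(coverage, degree). Returns chrom, pos, n_meth, n_unmeth."""
    if not (0 < covered_fraction <= 1):
        raise ValueError("covered_fraction must be in (0,1]")
    rng = stage_rng(seed, f"rrbs:{condition[0]}:{condition[1]}")
    cond = methylome.condition(*condition)
    frames = []
    for chrom, cpgs in genome.cpg_positions.items():
        covered = rng.random(len(cpgs)) < covered_fraction
        pos = cpgs[covered]
        if len(pos) == 0:
            continue
        p = nb_size / (nb_size + rrbs_mean_cov)
        cov = rng.negative_binomial(nb_size, p, size=len(pos))
        deg = cond[chrom][covered]
        n_meth = rng.binomial(cov, deg)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "n_meth": n_meth, "n_unmeth": cov - n_meth,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "n_meth", "n_unmeth"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# RNA-seq


def mean_promoter_degree(
    genome: ToyGenome, cond_degrees: Mapping[str, np.ndarray]
) -> pd.Series:
    """Mean methylation degree over each gene's promoter CpGs (0 if none)."""
    vals = {}
    for gene in genome.genes:
        cpgs = genome.cpg_positions[gene.chrom]
        s, e = promoter_window(gene)
        lo, hi = np.searchsorted(cpgs, [s, e])
        vals[gene.gene_id] = (
            float(cond_degrees[gene.chrom][lo:hi].mean()) if hi > lo else 0.0
        )
    return pd.Series(vals, name="promoter_degree")


def simulate_rnaseq(
    genome: ToyGenome,
    methylome: MethylomeTruth,
    params: SimulationParams,
    condition: tuple[str, str],
    seed: int = 0,
) -> pd.Series:
    """Per-gene counts: gene mean is a fixed gene baseline times
    exp(-expr_beta * mean promoter methylation), scaled so expected totals
    match ``rnaseq_depth`` at baseline. Counts are negative-binomial with
    dispersion ``nb_dispersion`` (Poisson when 0).
    """
    base_rng = stage_rng(seed, "rnaseq:baseline")
    n_genes = len(genome.genes)
    gene_ids = [g.gene_id for g in genome.genes]
    baseline = np.exp(base_rng.normal(0.0, 1.0, size=n_genes))
    scale = params.rnaseq_depth / baseline.sum() if baseline.sum() > 0 else 0.0

    deg = mean_promoter_degree(genome, methylome.condition(*condition))
    mu = scale * baseline * np.exp(-params.expr_beta * deg.loc[gene_ids].to_numpy())

    rng = stage_rng(seed, f"rnaseq:{condition[0]}:{condition[1]}")
    phi = params.nb_dispersion
    if phi <= 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = np.where(mu > 0, rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12))), 0)
    return pd.Series(counts.astype(np.int64), index=pd.Index(gene_ids, name="gene_id"),
                     name=f"{condition[0]}_{condition[1]}")


# ---------------------------------------------------------------------------
# whole-study convenience


@dataclass
class SimulatedStudy:
    genome: ToyGenome
    methylome: MethylomeTruth
    capture: dict[str, FragmentSet]         # sample_id -> fragments (with dups)
    rrbs: pd.DataFrame                      # QC library (control, first cell line)
    rnaseq: pd.DataFrame                    # genes x samples
    params: SimulationParams
    seed: int

    @property
    def control_samples(self) -> list[str]:
        return [f"{cl}_control" for cl in CELL_LINES]

    def design(self) -> pd.DataFrame:
        rows = [(f"{cl}_{tr}", cl, tr) for cl, tr in CONDITIONS]
        return pd.DataFrame(rows, columns=["sample", "block", "treatment"])


def simulate_study(
    genome_kwargs: dict | None = None,
    methylome_kwargs: dict | None = None,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> SimulatedStudy:
    """Generate the full four-sample study (2 cell lines x control/treated)
    plus the RRBS QC library taken from the first cell line's control."""
    params = params or SimulationParams()
    genome = generate_genome(seed=seed, **(genome_kwargs or {}))
    methylome = generate_methylome(genome, seed=seed, **(methylome_kwargs or {}))
    capture = {
        f"{cl}_{tr}": simulate_methylcap(genome, methylome, params, (cl, tr), seed=seed)
        for cl, tr in CONDITIONS
    }
    rrbs = simulate_rrbs(
        methylome, genome,
        rrbs_mean_cov=params.rrbs_mean_cov,
        covered_fraction=params.rrbs_covered_fraction,
        condition=(CELL_LINES[0], "control"),
        seed=seed, nb_size=params.rrbs_nb_size,
    )
    rnaseq = pd.concat(
        [simulate_rnaseq(genome, methylome, params, (cl, tr), seed=seed)
         for cl, tr in CONDITIONS], axis=1,
    )
    return SimulatedStudy(genome, methylome, capture, rrbs, rnaseq, params, seed)


def truth_tables(study: SimulatedStudy) -> dict[str, pd.DataFrame]:
    """Export ground truth: regulated genes, affected CpGs, per-condition
    degrees — written alongside every simulated data set."""
    reg = pd.DataFrame({"gene_id": sorted(study.methylome.regulated_genes)})
    rows = []
    for chrom, cpgs in study.genome.cpg_positions.items():
        mask = study.methylome.affected[chrom]
        rec = {"chrom": chrom, "pos": cpgs, "affected": mask}
        for (cl, tr), cond in study.methylome.degrees.items():
            rec[f"degree_{cl}_{tr}"] = cond[chrom]
        rows.append(pd.DataFrame(rec))
    degrees = pd.concat(rows, ignore_index=True)
    return {"regulated_genes": reg, "cpg_truth": degrees}
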