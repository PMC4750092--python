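"""Methylation Peak calling calibrated against RRBS.

The caller pools the deduplicated control libraries into a per-base
coverage track, scans candidate coverage thresholds (default 1..20) by
splitting RRBS CpGs into capture-"methylated" (coverage >= t) vs
"unmethylated" groups and scoring the split with a two-group
Kruskal-Wallis rank-sum test, then defines peaks as maximal runs where
every base meets the chosen threshold, trimmed so that each peak starts
and ends with a complete CpG dinucleotide.

The >= t convention is used both for CpG classification and for the peak
definition; the threshold scan makes the two conventions differ only by an
index shift. Threshold selection keys on the H statistic (same ordering as
the p-value but immune to p underflow), breaking ties toward the smallest
threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, FragmentSet


@dataclass
class CoverageTrack:
    chrom: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if (self.values < 0).any():
            raise ValueError("coverage must be non-negative")


@dataclass
class CalibrationResult:
    table: pd.DataFrame  # columns: threshold, H, p, n_methylated, n_unmethylated
    chosen_t: int

    @property
    def thresholds(self) -> np.ndarray:
        return self.table["threshold"].to_numpy()


@dataclass
class MethylationPeak:
    peak_id: str
    chrom: str
    start: int
    end: int
    n_cpg: int
    counts: dict[str, int] = field(default_factory=dict)
    p: float | None = None

    def __post_init__(self) -> None:
        if self.n_cpg < 1:
            raise ValueError("peak must contain at least one CpG")
        if not (0 <= self.start < self.end):
            raise ValueError("invalid peak interval")


def dedup_fragments(fragset: FragmentSet) -> FragmentSet:
    """Keep one representative per distinct (chrom, start, end) fragment —
    identically placed paired-end inserts are presumed PCR duplicates. The
    result is sorted, hence order-independent."""
    frame = (
        fragset.frame.drop_duplicates(["chrom", "start", "end"])
        .sort_values(["chrom", "start", "end"], kind="mergesort")
        .reset_index(drop=True)
    )
    return FragmentSet(fragset.sample_id, frame)


def pile_coverage(
    fragment_sets: Sequence[FragmentSet], chrom: str, chrom_length: int
) -> CoverageTrack:
    """Summed per-base coverage of the pooled (control) samples' fragments."""
    delta = np.zeros(chrom_length + 1, dtype=np.int64)
    for fs in fragment_sets:
        sub = fs.frame[fs.frame["chrom"] == chrom]
        if sub.empty:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if starts.min() < 0 or ends.max() > chrom_length:
            raise ValueError(
                f"fragment outside {chrom}:[0,{chrom_length}) in {fs.sample_id}"
            )
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends, -1)
    return CoverageTrack(chrom, np.cumsum(delta[:-1]))


def rank_sum_2group(values_a, values_b) -> tuple[float, float]:
    """Two-group Kruskal-Wallis H with tie correction; p from chi-square
    (1 df). Returns (nan, nan) if either group is empty, and (0, 1) when
    every observation is tied."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        return (float("nan"), float("nan"))
    pooled = np.concatenate([a, b])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    ra, rb = ranks[: len(a)], ranks[len(a):]
    h = (12.0 / (n * (n + 1))) * (
        len(a) * (ra.mean() - (n + 1) / 2) ** 2
        + len(b) * (rb.mean() - (n + 1) / 2) ** 2
    )
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction <= 0:  # all observations identical
        return (0.0, 1.0)
    h /= correction
    return (float(h), float(stats.chi2.sf(h, df=1)))


def calibrate_threshold(
    degrees, coverage, thresholds: Sequence[int] = tuple(range(1, 21))
) -> CalibrationResult:
    """Scan candidate coverage thresholds against the RRBS gold standard.

    For each t, CpGs with capture coverage >= t form the "methylated"
    group and the rest the "unmethylated" group; the groups' bisulfite
    degrees are compared by Kruskal-Wallis. The t with the clearest
    separation (largest H, equivalently smallest p) wins; ties break to
    the smallest t. Thresholds leaving either group empty are skipped.
    """
    deg = np.asarray(degrees, dtype=float)
    cov = np.asarray(coverage, dtype=float)
    if deg.shape != cov.shape:
        raise ValueError("degrees and coverage must align")
    rows = []
    for t in thresholds:
        meth = cov >= t
        h, p = rank_sum_2group(deg[meth], deg[~meth])
        rows.append({
            "threshold": int(t), "H": h, "p": p,
            "n_methylated": int(meth.sum()), "n_unmethylated": int((~meth).sum()),
        })
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["H"])
    if valid.empty:
        raise ValueError("no informative threshold: every split left a group empty")
    best = valid.sort_values(["H", "threshold"], ascending=[False, True]).iloc[0]
    return CalibrationResult(table, int(best["threshold"]))


def call_peaks(
    track: CoverageTrack,
    chosen_t: int,
    cpg_positions: np.ndarray,
    id_offset: int = 0,
) -> list[MethylationPeak]:
    """Maximal runs with coverage >= chosen_t, trimmed to [first CpG start,
    last CpG start + 2). Runs containing no complete CpG are dropped.
    Peak ids continue from ``id_offset``."""
    mask = track.values >= chosen_t
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    run_starts, run_ends = edges[::2], edges[1::2]
    cpg = np.asarray(cpg_positions)
    peaks: list[MethylationPeak] = []
    lo = np.searchsorted(cpg, run_starts, side="left")
    # CpGs fully inside: pos + 2 <= run_end  <=>  pos <= run_end - 2
    hi = np.searchsorted(cpg, run_ends - 2, side="right")
    k = id_offset
    for s, e, i, j in zip(run_starts, run_ends, lo, hi):
        if j > i:
            k += 1
            peaks.append(MethylationPeak(
                peak_id=f"peak_{k}",
                chrom=track.chrom,
                start=int(cpg[i]),
                end=int(cpg[j - 1]) + 2,
                n_cpg=int(j - i),
            ))
    return peaks


def call_peaks_genome(
    tracks: Mapping[str, CoverageTrack],
    chosen_t: int,
    cpg_positions: Mapping[str, np.ndarray],
) -> list[MethylationPeak]:
    """Call peaks chromosome by chromosome with genome-wide sequential ids."""
    peaks: list[MethylationPeak] = []
    for chrom in sorted(tracks):
        peaks.extend(
            call_peaks(tracks[chrom], chosen_t, cpg_positions[chrom],
                       id_offset=len(peaks))
        )
    return peaks


def peaks_frame(peaks: Sequence[MethylationPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.peak_id, p.chrom, p.start, p.end, p.n_cpg) for p in peaks],
        columns=["peak_id", "chrom", "start", "end", "n_cpg"],
    )


def count_fragments_per_peak(
    fragment_sets: Mapping[str, FragmentSet],
    peaks: Sequence[MethylationPeak],
) -> tuple[CountMatrix, dict[str, int]]:
    """Per-sample fragment counts per peak plus noise library sizes.

    A fragment is counted for every peak it overlaps by >= 1 bp (capture
    enrichment is regional, so a straddling fragment is evidence for both);
    a fragment overlapping no peak at all is a "noise read". Peaks must be
    disjoint. Updates each FragmentSet's noise_size in place as well.
    """
    by_chrom: dict[str, list[MethylationPeak]] = {}
    for pk in peaks:
        by_chrom.setdefault(pk.chrom, []).append(pk)
    starts_by_chrom: dict[str, np.ndarray] = {}
    ends_by_chrom: dict[str, np.ndarray] = {}
    idx_by_chrom: dict[str, np.ndarray] = {}
    order = {pk.peak_id: i for i, pk in enumerate(peaks)}
    for chrom, pks in by_chrom.items():
        pks.sort(key=lambda p: p.start)
        starts = np.array([p.start for p in pks])
        ends = np.array([p.end for p in pks])
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping peaks on {chrom}")
        starts_by_chrom[chrom] = starts
        ends_by_chrom[chrom] = ends
        idx_by_chrom[chrom] = np.array([order[p.peak_id] for p in pks])

    sample_ids = list(fragment_sets)
    counts = np.zeros((len(peaks), len(sample_ids)), dtype=np.int64)
    noise_sizes: dict[str, int] = {}
    for j, sid in enumerate(sample_ids):
        fs = fragment_sets[sid]
        assigned = 0
        for chrom, sub in fs.frame.groupby("chrom", sort=False):
            if chrom not in starts_by_chrom:
                continue
            fstart = sub["start"].to_numpy()
            fend = sub["end"].to_numpy()
            pstarts = starts_by_chrom[chrom]
            pends = ends_by_chrom[chrom]
            # peaks overlapping [fs, fe): those with end > fs and start < fe
            lo = np.searchsorted(pends, fstart, side="right")
            hi = np.searchsorted(pstarts, fend, side="left")
            multiplicity = hi - lo
            assigned += int((multiplicity > 0).sum())
            remaining = multiplicity.copy()
            offset = 0
            while (remaining > 0).any():
                sel = remaining > 0
                peak_idx = idx_by_chrom[chrom][lo[sel] + offset]
                np.add.at(counts[:, j], peak_idx, 1)
                remaining -= 1
                offset += 1
        noise = fs.total_size - assigned
        noise_sizes[sid] = noise
        fs.noise_size = noise

    frame = pd.DataFrame(
        counts, index=pd.Index([p.peak_id for p in peaks], name="peak_id"),
        columns=sample_ids,
    )
    for pk, row in zip(peaks, counts):
        pk.counts = dict(zip(sample_ids, (int(v) for v in row)))
    matrix = CountMatrix(frame, pd.Series(noise_sizes, name="noise_size"))
    return matrix, noise_sizes
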