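"""File formats, coordinate conventions and shared domain records.

Every coordinate inside the package is 0-based, half-open ``[start, end)``
— the BED convention. GTF/GFF input (1-based, end-inclusive) is converted
on read and converted back on write, so the two conversions compose to the
identity. MethylCap fragments are treated as unstranded insert intervals:
the capture step enriches double-stranded fragments, and the analysis
counts fragments, not stranded reads.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

STRANDS = ("+", "-", ".")

FRAGMENT_COLUMNS = ["chrom", "start", "end"]


class FormatError(ValueError):
    """A file did not conform to its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene with exon structure and a strand-derived TSS.

    The TSS is the leftmost exon start on the + strand and the rightmost
    exon end minus one (the last transcribed base) on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[GenomicInterval]
    transcripts: dict[str, list[GenomicInterval]] | None = None

    @classmethod
    def from_exons(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        exons: Sequence[GenomicInterval],
        transcripts: dict[str, list[GenomicInterval]] | None = None,
    ) -> "GeneModel":
        if strand not in ("+", "-"):
            raise ValueError(f"gene {gene_id}: strand must be + or -, got {strand!r}")
        if not exons:
            raise ValueError(f"gene {gene_id}: needs at least one exon")
        exons = sorted(exons, key=lambda e: (e.start, e.end))
        tss = exons[0].start if strand == "+" else exons[-1].end - 1
        return cls(gene_id, chrom, strand, tss, list(exons), transcripts)

    @property
    def span(self) -> GenomicInterval:
        """Gene body: first exon start through last exon end."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


class FragmentSet:
    """One sample's non-duplicate MethylCap fragment intervals.

    Fragments are held as a (chrom, start, end) DataFrame for vectorised
    coverage piling and counting. ``noise_size`` (fragments overlapping no
    Methylation Peak) is filled in late, by the peak-counting step.
    """

    def __init__(self, sample_id: str, frame: pd.DataFrame, noise_size: int | None = None):
        frame = frame.reset_index(drop=True)
        missing = [c for c in FRAGMENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"fragment frame missing columns {missing}")
        bad = frame["start"] >= frame["end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            row = frame.iloc[i]
            raise ValueError(
                f"fragment {row.chrom}:{row.start}-{row.end} has start >= end"
            )
        if (frame["start"] < 0).any():
            raise ValueError("negative fragment start")
        self.sample_id = sample_id
        self.frame = frame[FRAGMENT_COLUMNS].copy()
        if noise_size is not None and noise_size > len(frame):
            raise ValueError("noise_size cannot exceed total_size")
        self.noise_size = noise_size

    @property
    def total_size(self) -> int:
        return len(self.frame)

    def intervals(self) -> Iterable[GenomicInterval]:
        for row in self.frame.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end))

    def __len__(self) -> int:
        return self.total_size

    def __repr__(self) -> str:
        return (
            f"FragmentSet({self.sample_id!r}, n={self.total_size}, "
            f"noise_size={self.noise_size})"
        )


@dataclass
class CountMatrix:
    """Features x samples count table plus per-sample normalisation sizes."""

    counts: pd.DataFrame  # index: feature ids, columns: sample ids
    norm_sizes: pd.Series | None = None  # per-sample denominators

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.norm_sizes is not None:
            if not self.norm_sizes.index.equals(self.counts.columns):
                self.norm_sizes = self.norm_sizes.reindex(self.counts.columns)
            if self.norm_sizes.isna().any():
                raise ValueError("norm_sizes missing for some samples")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class PipelineConfig:
    """Tunable constants of the pipeline.

    Defaults follow the field's standard conventions: FDR 0.1, promoters
    from 2000 bp upstream to 500 bp downstream of the TSS, gene deserts
    strictly longer than 500 kb, candidate coverage thresholds 1..20,
    minimum RRBS coverage 10, and 1000 permutation iterations.
    """

    fdr_q: float = 0.1
    promoter_up: int = 2000
    promoter_down: int = 500
    desert_min_len: int = 500_000
    threshold_range: tuple[int, ...] = tuple(range(1, 21))
    rrbs_min_cov: int = 10
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must be in (0,1)")
        for name in ("promoter_up", "promoter_down", "desert_min_len", "rrbs_min_cov",
                     "n_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        tr = tuple(int(t) for t in self.threshold_range)
        if not tr or list(tr) != sorted(set(tr)) or tr[0] < 1:
            raise ValueError("threshold_range must be nonempty, ascending, positive")
        self.threshold_range = tr

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "threshold_range" in data:
            data["threshold_range"] = tuple(data["threshold_range"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["threshold_range"] = list(self.threshold_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def asdict(self) -> dict:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["threshold_range"] = list(self.threshold_range)
        return data


# ---------------------------------------------------------------------------
# fragment BED


def read_fragments(path: str | Path, sample_id: str | None = None) -> FragmentSet:
    """Read a BED-like file of mapped fragment intervals.

    Lines are tab-separated ``chrom start end`` (extra columns ignored);
    comment lines starting with '#' are skipped. Malformed lines raise
    :class:`FormatError` naming the 1-based line number.
    """
    path = Path(path)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if not (0 <= start < end):
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {parts[0]}:{start}-{end}"
                )
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
    frame = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    return FragmentSet(sample_id or path.stem, frame)


def write_fragments(fragset: FragmentSet, path: str | Path) -> None:
    fragset.frame.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene annotation (GTF or simplified TSV)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_exons(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = parts[:9]
            if feature != "exon":
                continue
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            attr = dict(_GTF_ATTR.findall(attrs))
            if "gene_id" not in attr or not attr["gene_id"]:
                raise FormatError(f"{path}:{lineno}: exon without gene_id")
            # GTF is 1-based end-inclusive -> 0-based half-open
            rows.append(
                (attr["gene_id"], attr.get("transcript_id", attr["gene_id"]),
                 chrom, strand, int(start1) - 1, int(end1))
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "chrom", "strand", "start", "end"]
    )


def _parse_tsv_exons(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "strand", "start", "end"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "transcript_id" not in frame.columns:
        frame["transcript_id"] = frame["gene_id"]
    bad = ~frame["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(f"{path}: unknown strand {frame.loc[bad, 'strand'].iloc[0]!r}")
    return frame[["gene_id", "transcript_id", "chrom", "strand", "start", "end"]]


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF/GFF (1-based, converted) or simplified TSV
    (already 0-based half-open). One GeneModel per gene_id; TSS derived from
    strand and exon extremes. A gene_id spanning two chromosomes is an error.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        exons = _parse_gtf_exons(path)
    else:
        exons = _parse_tsv_exons(path)
    if exons.empty:
        return []
    genes: list[GeneModel] = []
    for gene_id, grp in exons.groupby("gene_id", sort=True):
        if grp["chrom"].nunique() > 1:
            raise FormatError(
                f"gene_id {gene_id!r} appears on multiple chromosomes: "
                f"{sorted(grp['chrom'].unique())}"
            )
        if grp["strand"].nunique() > 1:
            raise FormatError(f"gene_id {gene_id!r} has conflicting strands")
        chrom = grp["chrom"].iloc[0]
        strand = grp["strand"].iloc[0]
        transcripts = {
            str(tid): [
                GenomicInterval(chrom, int(s), int(e), strand)
                for s, e in zip(tgrp["start"], tgrp["end"])
            ]
            for tid, tgrp in grp.groupby("transcript_id")
        }
        # gene-level exon set: union of distinct exon coordinates
        distinct = grp[["start", "end"]].drop_duplicates().sort_values(["start", "end"])
        ex = [GenomicInterval(chrom, int(s), int(e), strand)
              for s, e in zip(distinct["start"], distinct["end"])]
        genes.append(GeneModel.from_exons(str(gene_id), chrom, strand, ex, transcripts))
    return genes


def write_gene_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF exon records (converting back to 1-based)."""
    with open(path, "w") as fh:
        for gene in genes:
            transcripts = gene.transcripts or {gene.gene_id: gene.exons}
            for tid, exons in transcripts.items():
                for ex in exons:
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
                    fh.write(
                        f"{gene.chrom}\tmethylcap\texon\t{ex.start + 1}\t{ex.end}\t."
                        f"\t{gene.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# peak BED


def write_peaks_bed(peaks: Sequence, path: str | Path) -> None:
    """Write Methylation Peaks as BED5. Score is -10*log10(p) clipped to
    [0, 1000] when the peak carries a p-value, else 0. Input need not be
    sorted; output is sorted by (chrom, start).
    """
    recs = []
    for pk in peaks:
        p = getattr(pk, "p", None)
        if p is None or (isinstance(p, float) and math.isnan(p)):
            score = 0
        else:
            score = int(min(1000.0, max(0.0, -10.0 * math.log10(max(p, 1e-300)))))
        recs.append((pk.chrom, pk.start, pk.end, pk.peak_id, score))
    recs.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score in recs:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\n")


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    """Read a peaks BED back into a (peak_id, chrom, start, end, score) frame."""
    frame = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "peak_id", "score"],
        dtype={"chrom": str, "start": int, "end": int, "peak_id": str},
    )
    if (frame["start"] >= frame["end"]).any():
        raise FormatError(f"{path}: interval with start >= end")
    return frame
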