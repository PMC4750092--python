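"""RRBS summarisation: per-CpG methylation degrees, coverage filtering and
the capture/bisulfite concordance QC.

Counts from the two strands of a CpG are summed into one record per CpG
start before the degree is computed (CpG methylation is palindromic).
Zero-coverage CpGs are retained with an undefined (NaN) degree rather than
being treated as unmethylated; the coverage filter removes them explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RRBS_COLUMNS = ["chrom", "pos", "n_meth", "n_unmeth"]

# degree bins: <=1%, nine deciles, >=99%
_BIN_EDGES = np.array([0.01] + [i / 10 for i in range(1, 10)] + [0.99])
_BIN_LABELS = (
    ["<=1%"]
    + [f"{lo}-{hi}%" for lo, hi in zip([1] + list(range(10, 100, 10)),
                                       list(range(10, 100, 10)) + [99])]
    + [">=99%"]
)


@dataclass(frozen=True)
class CpGMethylation:
    """Bisulfite counts at one CpG; degree = n_meth / coverage."""

    chrom: str
    pos: int
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("negative bisulfite counts")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def degree(self) -> float:
        if self.coverage == 0:
            return float("nan")
        return self.n_meth / self.coverage


def summarize_cpg(raw: pd.DataFrame) -> pd.DataFrame:
    """Merge per-strand records by (chrom, pos) and compute degrees.

    Returns a frame with chrom, pos, n_meth, n_unmeth, coverage and degree
    (NaN where coverage is zero), one row per CpG, sorted by position.
    """
    missing = [c for c in RRBS_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"RRBS table missing columns {missing}")
    if (raw[["n_meth", "n_unmeth"]].to_numpy() < 0).any():
        raise ValueError("negative bisulfite counts")
    merged = (
        raw.groupby(["chrom", "pos"], as_index=False, sort=True)[["n_meth", "n_unmeth"]]
        .sum()
    )
    merged["coverage"] = merged["n_meth"] + merged["n_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        merged["degree"] = np.where(
            merged["coverage"] > 0, merged["n_meth"] / merged["coverage"], np.nan
        )
    return merged


def filter_covered(table: pd.DataFrame, min_cov: int = 10) -> pd.DataFrame:
    """Retain only CpGs covered by at least ``min_cov`` reads."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if "coverage" not in table.columns:
        table = summarize_cpg(table)
    return table[table["coverage"] >= min_cov].reset_index(drop=True)


def degree_bin(degrees: np.ndarray) -> np.ndarray:
    """Bin index for each degree: 0 = '<=1%', 11 = '>=99%'."""
    return np.digitize(np.asarray(degrees, dtype=float), _BIN_EDGES, right=True)


def concordance_report(
    rrbs_table: pd.DataFrame, capture_coverage: pd.DataFrame
) -> pd.DataFrame:
    """Capture-coverage summary per RRBS-degree bin.

    ``capture_coverage`` carries (chrom, pos, capture_cov) — the MethylCap
    pileup value at each CpG. CpGs present in both tables are binned by
    bisulfite degree (<=1%, deciles, >=99%); per bin the report gives n,
    mean and median capture coverage and the zero-coverage fraction. Higher
    bins having more capture coverage is the concordance the QC looks for.
    """
    if "degree" not in rrbs_table.columns:
        rrbs_table = summarize_cpg(rrbs_table)
    shared = rrbs_table.merge(capture_coverage, on=["chrom", "pos"], how="inner")
    shared = shared[shared["coverage"] > 0]
    if shared.empty:
        raise ValueError("no CpGs shared between RRBS table and capture coverage")
    shared = shared.assign(bin=degree_bin(shared["degree"].to_numpy()))
    rows = []
    for b, grp in shared.groupby("bin", sort=True):
        cov = grp["capture_cov"].to_numpy(dtype=float)
        rows.append({
            "bin": _BIN_LABELS[int(b)],
            "bin_index": int(b),
            "n": len(grp),
            "mean_capture_cov": float(cov.mean()),
            "median_capture_cov": float(np.median(cov)),
            "frac_zero_capture": float((cov == 0).mean()),
        })
    report = pd.DataFrame(rows)
    assert int(report["n"].sum()) == len(shared)
    return report


def read_rrbs_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in RRBS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return table


def write_rrbs_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
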