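"""Paired negative-binomial differential testing with bespoke normalisation.

MethylCap counts are normalised by the "noise" library size — the number
of fragments falling outside all Methylation Peaks — on the rationale that
a demethylating treatment redistributes capture away from peaks, so
between-peak reads are the stable part of the library. RNA-seq counts are
normalised by an iterative chi-square goodness-of-fit procedure that
estimates relative depths from the least-differential features.

The test itself is a per-feature NB log-linear model with a cell-line
blocking factor and a treatment factor, fit by iteratively reweighted
least squares simultaneously across all features; p-values come from the
likelihood-ratio test of the treatment coefficient (1 df chi-square). With
two blocks x two treatments there is a single residual degree of freedom,
so only a common dispersion, estimated by maximising the Cox-Reid adjusted
profile likelihood, is identifiable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, FragmentSet

_LN2 = math.log(2.0)
_POISSON_PHI = 1e-8  # below this, dispersion is treated as exactly Poisson


class ZeroNoiseError(ValueError):
    """A sample had no noise reads; fall back to total_size explicitly."""


@dataclass
class DesignInfo:
    samples: list[str]
    block: list[str]
    treatment: list[str]  # "control" / "treated"
    offsets: np.ndarray   # log normalisation size per sample

    def __post_init__(self) -> None:
        n = len(self.samples)
        if not (len(self.block) == len(self.treatment) == n):
            raise ValueError("design columns must align")
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.shape != (n,) or not np.isfinite(self.offsets).all():
            raise ValueError("offsets must be finite, one per sample")
        if len(set(self.block)) < 2 or len(set(self.treatment)) != 2:
            raise ValueError("paired analysis needs >=2 blocks and 2 treatments")

    def model_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(full, reduced) design matrices: intercept + block dummies
        (+ treatment indicator in the full model)."""
        blocks = sorted(set(self.block))
        n = len(self.samples)
        cols = [np.ones(n)]
        for b in blocks[1:]:
            cols.append(np.array([1.0 if x == b else 0.0 for x in self.block]))
        reduced = np.column_stack(cols)
        treat = np.array([1.0 if t == "treated" else 0.0 for t in self.treatment])
        full = np.column_stack([reduced, treat])
        return full, reduced


@dataclass
class DispersionEstimate:
    phi: float
    method: str = "common-CR-APL"
    low_confidence: bool = False


def noise_offsets(fragment_sets: dict[str, FragmentSet]) -> pd.Series:
    """log(noise library size) per sample — the conservative normaliser."""
    sizes = {}
    for sid, fs in fragment_sets.items():
        if fs.noise_size is None:
            raise ValueError(f"sample {sid}: noise_size not set; count peaks first")
        if fs.noise_size == 0:
            raise ZeroNoiseError(
                f"sample {sid}: zero noise reads; re-run with total_size offsets "
                "(offsets=log(total_size)) and flag the substitution"
            )
        sizes[sid] = math.log(fs.noise_size)
    return pd.Series(sizes, name="offset")


def gof_normalize(counts: pd.DataFrame | CountMatrix, max_iter: int = 10) -> pd.Series:
    """Relative sequencing-depth factors from a chi-square-like
    goodness-of-fit statistic.

    Iteratively: estimate depths from column sums, score every feature by
    its Poisson goodness of fit to those depths, keep the features between
    the 25th and 75th GOF percentiles (the least differential ones), and
    re-estimate depths from the kept set until it stabilises. Factors are
    rescaled to mean 1.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    x = counts.to_numpy(dtype=float)
    if x.sum() == 0:
        raise ValueError("all-zero count matrix")
    d = x.sum(axis=0) / x.sum()
    kept_prev: np.ndarray | None = None
    kept = np.ones(x.shape[0], dtype=bool)
    for _ in range(max_iter):
        rowsum = x.sum(axis=1)
        nonzero = rowsum > 0
        expected = rowsum[:, None] * d[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            gof = np.where(
                nonzero[:, None], (x - expected) ** 2 / np.maximum(expected, 1e-300), 0.0
            ).sum(axis=1)
        q25, q75 = np.percentile(gof[nonzero], [25, 75])
        kept = nonzero & (gof >= q25) & (gof <= q75)
        if kept.sum() == 0:
            kept = nonzero
        d = x[kept].sum(axis=0) / x[kept].sum()
        if kept_prev is not None and np.array_equal(kept, kept_prev):
            break
        kept_prev = kept
    factors = d / d.mean()
    return pd.Series(factors, index=counts.columns, name="depth_factor")


# ---------------------------------------------------------------------------
# batched NB GLM


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-feature NB (or Poisson when phi ~ 0) log-likelihood, summed over
    samples. y, mu: (F, S)."""
    mu = np.maximum(mu, 1e-300)
    if phi < _POISSON_PHI:
        ll = y * np.log(mu) - mu - gammaln(y + 1)
    else:
        r = 1.0 / phi
        ll = (
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
    return ll.sum(axis=1)


def _irls_fit(
    y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    phi: float,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB log-linear models for all features at once.

    y: (F, S) counts; X: (S, P); offsets: (S,) log sizes.
    Returns (beta (F,P), mu (F,S), loglik (F,), converged (F,)).
    """
    F, S = y.shape
    P = X.shape[1]
    # initialise at the offset-adjusted mean rate
    mean_rate = np.maximum(y, 0.5).mean(axis=1) / np.exp(offsets).mean()
    beta = np.zeros((F, P))
    beta[:, 0] = np.log(mean_rate)
    converged = np.zeros(F, dtype=bool)
    mu = np.exp(beta @ X.T + offsets[None, :])
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        mu_a = np.clip(np.exp(beta[active] @ X.T + offsets[None, :]), 1e-10, 1e12)
        w = mu_a / (1.0 + phi * mu_a)  # working weights (log link, NB variance)
        z = (beta[active] @ X.T) + (y[active] - mu_a) / mu_a  # working response - offset
        XtWX = np.einsum("fs,sp,sq->fpq", w, X, X)
        XtWz = np.einsum("fs,sp,fs->fp", w, X, z)
        XtWX += 1e-10 * np.eye(P)[None, :, :]
        new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = new_beta - beta[active]
        # damp huge steps to keep exp() in range
        norm = np.abs(step).max(axis=1, keepdims=True)
        step = step * np.where(norm > 10, 10 / np.maximum(norm, 1e-300), 1.0)
        beta[active] = beta[active] + step
        done = np.abs(step).max(axis=1) < tol
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
    mu = np.clip(np.exp(beta @ X.T + offsets[None, :]), 1e-300, 1e12)
    ll = _nb_loglik(y, mu, phi)
    return beta, mu, ll, converged


def _cr_adjustment(mu: np.ndarray, X: np.ndarray, phi: float) -> np.ndarray:
    """Cox-Reid adjustment 0.5*logdet(X'WX) per feature."""
    w = mu / (1.0 + phi * mu)
    XtWX = np.einsum("fs,sp,sq->fpq", w, X, X)
    sign, logdet = np.linalg.slogdet(XtWX + 1e-12 * np.eye(X.shape[1])[None])
    return 0.5 * logdet


def estimate_common_dispersion(
    counts: pd.DataFrame | CountMatrix,
    design: DesignInfo,
    grid: np.ndarray | None = None,
) -> DispersionEstimate:
    """Common NB dispersion maximising the summed Cox-Reid adjusted profile
    likelihood over features, on a log grid refined by golden-section
    search. Deterministic."""
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    y = counts.to_numpy(dtype=float)
    y = y[y.sum(axis=1) > 0]
    if y.shape[0] == 0:
        raise ValueError("no nonzero features")
    X, _ = design.model_matrices()
    if y.shape[1] - X.shape[1] < 1:
        raise ValueError("fewer than 1 residual degree of freedom")
    offsets = design.offsets

    def apl(phi: float) -> float:
        _, mu, ll, _ = _irls_fit(y, X, offsets, phi)
        return float((ll - _cr_adjustment(mu, X, phi)).sum())

    if grid is None:
        grid = np.geomspace(1e-4, 4.0, 15)
    vals = np.array([apl(p) for p in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    # golden-section refinement on log scale
    gr = (math.sqrt(5) - 1) / 2
    a, b = math.log(lo), math.log(hi)
    c, dpt = b - gr * (b - a), a + gr * (b - a)
    fc, fd = apl(math.exp(c)), apl(math.exp(dpt))
    for _ in range(25):
        if b - a < 1e-3:
            break
        if fc > fd:
            b, dpt, fd = dpt, c, fc
            c = b - gr * (b - a)
            fc = apl(math.exp(c))
        else:
            a, c, fc = c, dpt, fd
            dpt = a + gr * (b - a)
            fd = apl(math.exp(dpt))
    phi = math.exp((a + b) / 2)
    return DispersionEstimate(phi=phi, low_confidence=y.shape[0] < 20)


def nb_paired_test(
    counts: pd.DataFrame | CountMatrix,
    design: DesignInfo,
    dispersion: DispersionEstimate | float,
) -> pd.DataFrame:
    """Likelihood-ratio test of the treatment effect per feature.

    Returns a frame with feature_id, logFC (log2, treated vs control), p,
    and a converged flag. Non-convergent features keep NaN p (excluded from
    BH downstream); all-zero features are the exact null (logFC 0, p 1).
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    phi = dispersion.phi if isinstance(dispersion, DispersionEstimate) else float(dispersion)
    y = counts.to_numpy(dtype=float)
    X_full, X_red = design.model_matrices()
    offsets = design.offsets

    beta_f, _, ll_f, conv_f = _irls_fit(y, X_full, offsets, phi)
    _, _, ll_r, conv_r = _irls_fit(y, X_red, offsets, phi)
    lrt = np.maximum(2.0 * (ll_f - ll_r), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    logfc = beta_f[:, -1] / _LN2
    converged = conv_f & conv_r

    allzero = y.sum(axis=1) == 0
    logfc[allzero] = 0.0
    p[allzero] = 1.0
    converged[allzero] = True
    p = np.where(converged, p, np.nan)
    return pd.DataFrame({
        "feature_id": counts.index,
        "logFC": logfc,
        "p": p,
        "converged": converged,
    }).set_index("feature_id")


def bh_adjust(results: pd.DataFrame, fdr_q: float = 0.1) -> pd.DataFrame:
    """Benjamini-Hochberg step-up q-values and significance flags.

    Features with undefined p (non-convergent fits) are excluded from the
    correction — they neither inflate nor deflate m — and come back with
    NaN q and significant=False.
    """
    out = results.copy()
    p = out["p"].to_numpy(dtype=float)
    valid = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    sig = np.zeros(len(p), dtype=bool)
    if valid.any():
        _, qv, _, _ = multipletests(p[valid], method="fdr_bh")
        q[valid] = qv
        sig[valid] = qv <= fdr_q
    out["q"] = q
    out["significant"] = sig
    return out


def differential_results(
    counts: pd.DataFrame | CountMatrix,
    design: DesignInfo,
    fdr_q: float = 0.1,
    dispersion: DispersionEstimate | float | None = None,
) -> tuple[pd.DataFrame, DispersionEstimate]:
    """Dispersion estimation + paired LRT + BH in one call."""
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, design)
    elif not isinstance(dispersion, DispersionEstimate):
        dispersion = DispersionEstimate(float(dispersion), method="fixed")
    res = bh_adjust(nb_paired_test(counts, design, dispersion), fdr_q)
    return res, dispersion
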