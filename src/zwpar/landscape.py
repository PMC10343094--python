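"""Chromosome-scale analysis of windowed tracks.

Tools for interpreting windowed statistics along a chromosome: rolling
means for visual smoothing, broken-line (segmented) regression to locate
change-points in the recombination landscape, Mann-Whitney group
comparisons, generalized least squares with AR(1) errors for regressions
between spatially autocorrelated window series, and detection of the
PAR/SLR boundary and of W-linked scaffolds from female:male coverage
ratios (females carry one Z, so normalized female coverage halves in the
sex-linked region and male coverage vanishes on W-specific sequence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .recmap import GenomicTrack

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentedFit",
    "Ar1GlsFit",
    "BoundaryCall",
    "rolling_mean",
    "changepoints",
    "mann_whitney",
    "gls_ar1",
    "boundary_from_coverage",
    "classify_scaffold",
]


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def rolling_mean(track: GenomicTrack, span_bp: float) -> GenomicTrack:
    """Centered positional rolling average of a windowed track.

    Each window's smoothed value is the mean over windows whose midpoints
    lie within span/2 of its own midpoint; near the edges the neighborhood
    simply shrinks to the available windows.
    """
    out_frames = []
    for chrom, sub in track.df.groupby("chrom", sort=False):
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
        if len(mids) > 1 and span_bp < np.min(np.diff(np.sort(mids))):
            raise ValueError("span smaller than one window")
        vals = sub["value"].to_numpy(dtype=float)
        half = span_bp / 2.0
        lo = np.searchsorted(mids, mids - half, side="left")
        hi = np.searchsorted(mids, mids + half, side="right")
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        sm = (csum[hi] - csum[lo]) / (hi - lo)
        new = sub.copy()
        new["value"] = sm
        out_frames.append(new)
    return GenomicTrack(pd.concat(out_frames, ignore_index=True))


# ---------------------------------------------------------------------------
# broken-line (segmented) regression
# ---------------------------------------------------------------------------

@dataclass
class SegmentedFit:
    """Broken-line regression fit: y = b0 + b1*x + sum_k d_k (x - psi_k)+.

    ``breakpoints`` are sorted and interior to the data span; ``slopes``
    has one entry per segment (K+1 for K breakpoints).  ``converged`` is
    False when the iteration hit max_iter or a breakpoint escaped the data
    span; the last iterate is still reported.
    """

    breakpoints: np.ndarray
    breakpoint_se: np.ndarray
    slopes: np.ndarray
    intercept: float
    converged: bool
    n_iter: int
    rss: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = self.intercept + self.slopes[0] * x
        for k, psi in enumerate(self.breakpoints):
            delta = self.slopes[k + 1] - self.slopes[k]
            y = y + delta * np.clip(x - psi, 0.0, None)
        return y


def _rss_brokenline(x: np.ndarray, y: np.ndarray, psi: np.ndarray) -> float:
    U = np.clip(x[:, None] - psi[None, :], 0.0, None)
    X = np.column_stack([np.ones_like(x), x, U])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _seed_breakpoints(x: np.ndarray, y: np.ndarray, K: int,
                      max_combos: int = 25_000) -> np.ndarray:
    """Breakpoint seeding for the locally convergent refinement.

    The linearized update only finds the optimum nearest its start, and
    broken-line RSS surfaces are multimodal, so seeding matters: scan all
    combinations of K positions on a coarse candidate grid and keep the
    lowest-RSS one.  When the combination count would exceed
    ``max_combos``, fall back to myopic forward selection.
    """
    from itertools import combinations
    from math import comb

    candidates = x[2:-2]
    stride = 1
    while comb(max(len(candidates) // stride, K), K) > max_combos:
        stride += 1
    coarse = candidates[::stride]
    if comb(len(coarse), K) <= max_combos:
        best, best_rss = None, np.inf
        for combo in combinations(coarse, K):
            rss = _rss_brokenline(x, y, np.asarray(combo))
            if rss < best_rss:
                best, best_rss = combo, rss
        return np.asarray(best, dtype=float)
    # forward selection fallback for large K
    psi: list[float] = []
    for _ in range(K):
        best, best_rss = None, np.inf
        for c in coarse:
            if psi and np.min(np.abs(np.asarray(psi) - c)) < 1e-9:
                continue
            rss = _rss_brokenline(x, y, np.sort(np.array(psi + [c])))
            if rss < best_rss:
                best, best_rss = c, rss
        psi.append(float(best))
    return np.sort(np.asarray(psi))


def changepoints(track: GenomicTrack, n_breakpoints: int,
                 tol: float = 1e-4, max_iter: int = 50,
                 init: np.ndarray | None = None) -> SegmentedFit:
    """Fit a broken-line regression to a windowed track.

    Iterative linearization (the algorithm behind standard segmented
    regression): given current psi, regress y on [1, x, U_k, V_k] with
    U_k = (x - psi_k)+ and V_k = -1{x > psi_k}, then update
    psi_k <- psi_k + gamma_k / delta_k where gamma_k, delta_k are the V and
    U coefficients; at the optimum gamma = 0.  Breakpoints are seeded by a
    coarse joint scan of candidate positions unless ``init`` is given;
    convergence is declared when every update is below ``tol`` of the data
    span (accepted updates never increase the residual sum of squares).

    Two breakpoints collapsing within one window triggers a refit with
    K-1 (warned); non-convergence yields a flagged fit, not an exception.
    """
    x = track.midpoints.astype(float)
    y = track.values.astype(float)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    K = int(n_breakpoints)
    if K < 1:
        raise ValueError("need at least one breakpoint")
    if len(x) < 2 * K + 2:
        raise ValueError(f"{len(x)} windows cannot support {K} breakpoints")
    order = np.argsort(x)
    x, y = x[order], y[order]
    span = x[-1] - x[0]
    min_gap = np.min(np.diff(x))
    psi = (_seed_breakpoints(x, y, K)
           if init is None else np.sort(np.asarray(init, dtype=float)))

    def rss_at(p):
        U = np.clip(x[:, None] - p[None, :], 0.0, None)
        X = np.column_stack([np.ones_like(x), x, U])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    converged = False
    it = 0
    rss_cur = rss_at(psi)
    for it in range(1, max_iter + 1):
        U = np.clip(x[:, None] - psi[None, :], 0.0, None)
        V = -(x[:, None] > psi[None, :]).astype(float)
        X = np.column_stack([np.ones_like(x), x, U, V])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        delta = beta[2: 2 + K]
        gamma = beta[2 + K:]
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(np.abs(delta) > 1e-12, gamma / delta, 0.0)
        # step-halving keeps the objective non-increasing (accepted moves)
        accepted = False
        for damp in range(12):
            cand = np.sort(np.clip(psi + step * 0.5**damp,
                                   x[0] + 1e-9, x[-1] - 1e-9))
            rss_new = rss_at(cand)
            if rss_new <= rss_cur * (1 + 1e-12):
                accepted = True
                break
        if not accepted:
            converged = True        # no improving move left: local optimum
            break
        moved = np.max(np.abs(cand - psi))
        psi, rss_cur = cand, rss_new
        if K > 1 and np.min(np.diff(psi)) < min_gap:
            logger.warning("breakpoints collapsed within one window; refitting with K-1")
            return changepoints(track, K - 1, tol=tol, max_iter=max_iter)
        if moved < tol * span:
            converged = True
            break

    # final design at the converged psi (gamma ~ 0)
    U = np.clip(x[:, None] - psi[None, :], 0.0, None)
    X = np.column_stack([np.ones_like(x), x, U])
    beta_f, rss_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_f
    rss = float(resid @ resid)
    slopes = np.concatenate([[beta_f[1]], beta_f[1] + np.cumsum(beta_f[2:])])
    # delta-method SE of psi_k: SE(gamma_k)/|delta_k| from the augmented fit
    psi_se = _breakpoint_se(x, y, psi, rss)
    if not converged:
        logger.warning("segmented fit did not converge in %d iterations", max_iter)
    return SegmentedFit(breakpoints=psi, breakpoint_se=psi_se,
                        slopes=slopes, intercept=float(beta_f[0]),
                        converged=converged, n_iter=it, rss=rss)


def _breakpoint_se(x, y, psi, rss) -> np.ndarray:
    K = len(psi)
    U = np.clip(x[:, None] - psi[None, :], 0.0, None)
    V = -(x[:, None] > psi[None, :]).astype(float)
    X = np.column_stack([np.ones_like(x), x, U, V])
    n, p = X.shape
    dof = max(n - p, 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        delta = beta[2: 2 + K]
        se_gamma = np.sqrt(np.diag(cov)[2 + K:])
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(np.abs(delta) > 1e-12, se_gamma / np.abs(delta), np.inf)
    except np.linalg.LinAlgError:
        return np.full(K, np.inf)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U for sample ``a`` versus ``b``, with two-sided p.

    Exact null enumeration when there are no ties and n_a * n_b <= 10^4;
    otherwise the normal approximation with continuity and tie
    corrections.  Returns (U_a, p); completely tied data give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (not has_ties and a.size * b.size <= 10_000) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# GLS with AR(1) errors
# ---------------------------------------------------------------------------

@dataclass
class Ar1GlsFit:
    """Maximum-likelihood GLS fit of y = X beta + e, e_t = phi e_{t-1} + u_t."""

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    phi: float
    loglik: float
    names: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        names = self.names or [f"x{i}" for i in range(len(self.params))]
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "t": self.tvalues, "p": self.pvalues}, index=names)


def _ar1_profile(phi: float, y: np.ndarray, X: np.ndarray):
    """Concentrated Gaussian log-likelihood at a given AR(1) parameter.

    Prais-Winsten whitening: first row scaled by sqrt(1-phi^2), the rest
    quasi-differenced; the Jacobian term (1/2) log(1-phi^2) keeps the
    first observation in the likelihood.
    """
    n = len(y)
    c = np.sqrt(1.0 - phi * phi)
    ys = np.empty_like(y)
    Xs = np.empty_like(X)
    ys[0] = c * y[0]
    Xs[0] = c * X[0]
    ys[1:] = y[1:] - phi * y[:-1]
    Xs[1:] = X[1:] - phi * X[:-1]
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    ll = (-0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
          + 0.5 * np.log(1.0 - phi * phi))
    return ll, beta, Xs, sigma2


def gls_ar1(y, X, names: list[str] | None = None,
            add_intercept: bool = True) -> Ar1GlsFit:
    """ML fit of a linear model with AR(1) errors on an ordered series.

    The AR parameter is profiled out: for each candidate phi the model is
    whitened (Prais-Winsten, first observation included) and beta solved
    by least squares; Brent search on (-1, 1) maximizes the concentrated
    log-likelihood.  Standard errors come from the whitened design at the
    ML phi; p-values are two-sided t with n - p degrees of freedom.

    Rows with missing values must be dropped by the caller (the series is
    assumed contiguous); a rank-deficient design raises.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        if names is not None:
            names = ["intercept", *names]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in y or X; drop incomplete rows first")

    res = optimize.minimize_scalar(lambda p: -_ar1_profile(p, y, X)[0],
                                   bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-8})
    phi = float(res.x)
    ll, beta, Xs, sigma2 = _ar1_profile(phi, y, X)
    n, p = X.shape
    # ML sigma2 is rss/n; use the dof-corrected version for SEs
    sigma2_dof = sigma2 * n / max(n - p, 1)
    cov = sigma2_dof * np.linalg.pinv(Xs.T @ Xs)
    bse = np.sqrt(np.diag(cov))
    tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=max(n - p, 1))
    return Ar1GlsFit(params=beta, bse=bse, tvalues=tvals, pvalues=pvals,
                     phi=phi, loglik=float(ll),
                     names=names or [f"x{i}" for i in range(p)])


# ---------------------------------------------------------------------------
# coverage-based boundary detection
# ---------------------------------------------------------------------------

@dataclass
class BoundaryCall:
    """Result of the coverage-ratio scan on one scaffold."""

    chrom: str
    boundary: tuple[int, int] | None     # interval bracketing the transition
    scaffold_class: str                  # PAR-like / Z-SLR / W-specific
    ratio_track: GenomicTrack = field(repr=False, default=None)


def classify_scaffold(cov_male: GenomicTrack, cov_female: GenomicTrack,
                      w_cutoff: float = 0.1) -> str:
    """Classify a scaffold from its median coverage ratios.

    median F:M near 1 -> PAR-like (both sexes diploid); near 0.5 -> Z-SLR
    (females hemizygous); median M:F below ``w_cutoff`` -> W-specific
    (males carry no W).
    """
    f = cov_female.values
    m = cov_male.values
    with np.errstate(divide="ignore", invalid="ignore"):
        mf = np.where(f > 0, m / f, np.inf)
        fm = np.where(m > 0, f / m, np.inf)
    if float(np.nanmedian(mf)) < w_cutoff:
        return "W-specific"
    med = float(np.nanmedian(fm))
    return "PAR-like" if med >= 0.75 else "Z-SLR"


def boundary_from_coverage(cov_male: GenomicTrack, cov_female: GenomicTrack,
                           high: float = 0.75, low: float = 0.6,
                           persistence: int = 5,
                           w_cutoff: float = 0.1) -> BoundaryCall:
    """Locate the PAR/SLR boundary from sex-averaged coverage ratios.

    Inputs are per-sex mean coverage tracks on one scaffold, each sample
    normalized to its own genome-wide mean before averaging, so the F:M
    ratio is ~1 where both sexes are diploid and ~0.5 where females are
    hemizygous.  The boundary is called at the last window with ratio >=
    ``high`` that is followed by at least ``persistence`` consecutive
    windows with ratio <= ``low``; the reported interval spans from the
    end of that window to the start of the first sustained-low window.
    Zero-coverage windows (assembly gaps) are ignored by the scan, so a
    gap at the transition is bracketed by the interval.  A scaffold with
    no such transition gets ``boundary=None`` and only a class label.
    """
    if not (cov_male.df[["chrom", "start", "end"]].to_numpy()
            == cov_female.df[["chrom", "start", "end"]].to_numpy()).all():
        raise ValueError("male and female coverage tracks must share windows")
    chrom = cov_male.df["chrom"].iloc[0]
    m = cov_male.values
    f = cov_female.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(m > 0, f / m, np.nan)
    ratio_track = GenomicTrack(cov_male.df.assign(value=ratio))
    cls = classify_scaffold(cov_male, cov_female, w_cutoff=w_cutoff)

    informative = ~np.isnan(ratio) & ((m > 0) | (f > 0))
    idx = np.where(informative)[0]
    boundary = None
    r = ratio[idx]
    for t in range(len(idx) - persistence):
        if r[t] >= high and np.all(r[t + 1: t + 1 + persistence] <= low):
            later_high = np.where(r[t + 1:] >= high)[0]
            # take the LAST qualifying high window: keep scanning
            boundary = (int(cov_male.df["end"].iloc[idx[t]]),
                        int(cov_male.df["start"].iloc[idx[t + 1]]))
            if later_high.size == 0:
                break
    return BoundaryCall(chrom=chrom, boundary=boundary,
                        scaffold_class=cls, ratio_track=ratio_track)
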