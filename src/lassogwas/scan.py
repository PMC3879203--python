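"""Step 1: the single-SNP mixed-model association scan (SMMA).

The model per SNP j is  y = 1*mu + x_j*beta_j + g + e  with a pedigree
polygenic effect g ~ N(0, A*sigma_g2) and e ~ N(0, I*sigma_e2).  Variance
components are estimated *once* on the null polygenic model (no SNP) by
REML and then held fixed across the whole scan, which turns every per-SNP
fit into a single linear solve.

The per-SNP solve goes through the mixed-model equations with the random
effect absorbed: with M_gg = I/sigma_e2 + A^-1/sigma_g2, the fixed-effect
system is F' P F b = F' P y where P = I/sigma_e2 - M_gg^-1/sigma_e2^2 and
F = [1, x_j].  P is SNP-independent, so it is factorised once and reused.
(An independent check in the test-suite confirms this equals direct GLS with
V = A*sigma_g2 + I*sigma_e2.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import optimize, stats

from .kinship import RelationshipMatrix


@dataclass
class VarianceComponents:
    """Null-model REML variance components (polygenic and residual)."""

    sigma_g2: float
    sigma_e2: float
    converged: bool = True
    loglik: float = np.nan

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_g2) or not np.isfinite(self.sigma_e2):
            raise ValueError("variance components must be finite")
        if self.sigma_g2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("need sigma_g2 >= 0 and sigma_e2 > 0")


@dataclass
class ScanResult:
    """Per-SNP scan output: effect, SE, t, P and -log10 P, plus a flag for
    SNPs that could not be tested (monomorphic after imputation)."""

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    neg_log10_p: np.ndarray
    flagged: np.ndarray  # boolean: untestable SNP

    def to_frame(self, snps: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "neg_log10_p": self.neg_log10_p,
                "flagged": self.flagged,
            }
        )
        if snps is not None:
            df = pd.concat(
                [snps[["snp_id", "chrom", "bp"]].reset_index(drop=True), df], axis=1
            )
        return df


def _as_A(A: RelationshipMatrix | np.ndarray) -> np.ndarray:
    return A.A if isinstance(A, RelationshipMatrix) else np.asarray(A, dtype=float)


def estimate_varcomps_null(
    y: np.ndarray, A: RelationshipMatrix | np.ndarray
) -> VarianceComponents:
    """REML variance components for  y = 1*mu + g + e,  g ~ N(0, A*sigma_g2).

    Works in the eigenbasis of A, where V = sigma_e2*I + sigma_g2*D is
    diagonal, and maximises the profile restricted log-likelihood over the
    ratio gamma = sigma_g2/sigma_e2 by bounded scalar search; sigma_e2 has a
    closed form given gamma.  The boundary gamma = 0 (no polygenic variance)
    is allowed.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 observations for REML")
    Am = _as_A(A)
    if Am.shape != (n, n):
        raise ValueError("A must be n x n aligned to y")
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("phenotype is constant; variance components undefined")
    d, U = np.linalg.eigh(Am)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def profile(log_gamma: float) -> tuple[float, float, float]:
        gamma = np.exp(log_gamma)
        v = 1.0 + gamma * d
        w = 1.0 / v
        xwx = float(np.sum(xt * xt * w))
        xwy = float(np.sum(xt * yt * w))
        ywy = float(np.sum(yt * yt * w))
        sse = max(ywy - xwy * xwy / xwx, 1e-300)
        s2e = sse / (n - 1)
        rll = -0.5 * (
            float(np.sum(np.log(v))) + np.log(xwx) + (n - 1) * (np.log(s2e) + 1.0)
        )
        return rll, s2e, gamma

    def neg(log_gamma: float) -> float:
        return -profile(log_gamma)[0]

    # coarse bracket then local refinement on log-gamma
    grid = np.linspace(-12.0, 8.0, 41)
    vals = np.array([neg(g) for g in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    rll, s2e, gamma = profile(float(res.x))
    # boundary: compare with gamma -> 0 (pure residual model)
    rll0, s2e0, _ = profile(-40.0)
    if rll0 >= rll:
        rll, s2e, gamma = rll0, s2e0, 0.0
    sigma_e2 = max(s2e, 1e-10 * vy)
    return VarianceComponents(
        sigma_g2=gamma * s2e, sigma_e2=sigma_e2, converged=bool(res.success), loglik=rll
    )


class ScanWorkspace:
    """SNP-independent pieces of the mixed-model-equation solve, built once
    per (A, variance-components) pair and reused across the scan."""

    def __init__(self, A: RelationshipMatrix | np.ndarray, vc: VarianceComponents, n: int):
        Am = _as_A(A)
        self.vc = vc
        if vc.sigma_g2 <= 1e-12 * vc.sigma_e2:
            self.P = np.eye(n) / vc.sigma_e2
        else:
            try:
                L = scipy.linalg.cho_factor(Am, lower=True)
            except scipy.linalg.LinAlgError:
                jitter = 1e-8 * float(np.mean(np.diag(Am)))
                L = scipy.linalg.cho_factor(Am + jitter * np.eye(n), lower=True)
            Ainv = scipy.linalg.cho_solve(L, np.eye(n))
            Mgg = np.eye(n) / vc.sigma_e2 + Ainv / vc.sigma_g2
            Mgg_inv = scipy.linalg.cho_solve(
                scipy.linalg.cho_factor(Mgg, lower=True), np.eye(n)
            )
            self.P = np.eye(n) / vc.sigma_e2 - Mgg_inv / vc.sigma_e2**2
        self.ones = np.ones(n)
        self.P1 = self.P @ self.ones
        self.s11 = float(self.ones @ self.P1)
        self.n = n


def _fit_columns(
    ws: ScanWorkspace, y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised 2x2 fixed-effect solves for every column of X."""
    Py = ws.P @ y
    s1y = float(ws.ones @ Py)
    PX = ws.P @ X
    s1x = ws.ones @ PX
    xPx = np.einsum("ij,ij->j", X, PX)
    xPy = X.T @ Py
    det = ws.s11 * xPx - s1x**2
    scale = ws.s11 * np.maximum(xPx, 1e-300)
    flagged = det <= 1e-12 * np.maximum(scale, 1e-300)
    det_safe = np.where(flagged, 1.0, det)
    beta = (ws.s11 * xPy - s1x * s1y) / det_safe
    var_beta = ws.s11 / det_safe
    se = np.sqrt(np.maximum(var_beta, 1e-300))
    t = beta / se
    df = ws.n - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    beta = np.where(flagged, 0.0, beta)
    se = np.where(flagged, np.nan, se)
    t = np.where(flagged, 0.0, t)
    p = np.where(flagged, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    return beta, se, t, p, flagged


def smma_single_snp(
    y: np.ndarray,
    x_j: np.ndarray,
    A: RelationshipMatrix | np.ndarray,
    vc: VarianceComponents,
) -> tuple[float, float, float, float]:
    """Effect, SE, t and two-sided P for one SNP with variance components
    held fixed (no per-SNP re-estimation).  df = n - 2."""
    y = np.asarray(y, dtype=float)
    ws = ScanWorkspace(A, vc, len(y))
    beta, se, t, p, flagged = _fit_columns(ws, y, np.asarray(x_j, dtype=float)[:, None])
    return float(beta[0]), float(se[0]), float(t[0]), float(p[0])


def scan(
    y: np.ndarray,
    G_coded: np.ndarray,
    A: RelationshipMatrix | np.ndarray,
    vc: VarianceComponents,
) -> ScanResult:
    """SMMA over every SNP column of ``G_coded``; one bad (constant) SNP is
    flagged with P = 1 and never aborts the scan."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(G_coded, dtype=float)
    ws = ScanWorkspace(A, vc, len(y))
    beta, se, t, p, flagged = _fit_columns(ws, y, X)
    with np.errstate(divide="ignore"):
        nlp = -np.log10(p)
    return ScanResult(beta, se, t, p, nlp, flagged)


def bonferroni_threshold(N: int, alpha: float = 0.05) -> float:
    """Genome-wise scan threshold on the -log10 P scale: -log10(alpha/N)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return float(-np.log10(alpha / N))


def select_top_k(scan_result: ScanResult, K: int = 500) -> np.ndarray:
    """Indices of the K smallest-P SNPs, ties broken by map order; the
    returned indices are in map order for design-matrix construction."""
    p = scan_result.p
    if K > len(p):
        raise ValueError(f"K={K} exceeds the number of scanned SNPs ({len(p)})")
    order = np.lexsort((np.arange(len(p)), p))
    chosen = order[:K]
    return np.sort(chosen)
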