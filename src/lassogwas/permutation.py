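"""Genome-wise significance threshold for SNP heritability by permutation.

The test statistic is max_j h_j^2 over the K SNPs in the multi-SNP model.
Each permutation shuffles the phenotype vector against the fixed design
matrix and relationship matrix — breaking both the SNP and the polygenic
associations — refits the EM-LASSO, and records the maximum heritability.
The genome-wise threshold at level alpha is the empirical (1 - alpha)
quantile (type-7 linear interpolation) of those maxima; an observed SNP is
declared significant when its h_j^2 strictly exceeds the threshold.

Per-permutation seeds are derived deterministically from the master seed,
and the eigendecomposition of A and the design cross-products are computed
once and shared across all refits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .kinship import RelationshipMatrix
from .lasso import KinshipFactor, LassoPriors, _em_fit, _marginal_beta, _Workspace


@dataclass
class PermutationNull:
    """Permutation null of the maximum SNP heritability and its threshold."""

    max_h2: np.ndarray
    alpha: float
    threshold: float
    seed: int
    n_perm: int
    n_not_converged: int = 0

    def __post_init__(self) -> None:
        if len(self.max_h2) != self.n_perm:
            raise ValueError("max_h2 length must equal n_perm")


def threshold_from_max(max_h2: np.ndarray, alpha: float) -> float:
    """Empirical (1 - alpha) quantile of the permutation maxima (type 7)."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    return float(np.quantile(np.asarray(max_h2, dtype=float), 1.0 - alpha))


class _PermFitter:
    """Refits the multi-SNP model on a permuted phenotype the same way the
    observed fit is produced: starting effects from the single-SNP GLS
    solve of the *permuted* phenotype under the same variance components
    (the single-SNP workspace is permutation-invariant, so each init costs
    one rotation), then the EM-LASSO with identical settings."""

    def __init__(
        self,
        ws: _Workspace,
        priors: LassoPriors,
        sigma_g2: float,
        sigma_e2: float,
        update_varcomps: bool,
        tol: float,
        max_iter: int,
    ):
        self.ws = ws
        self.priors = priors
        self.sigma_g2 = sigma_g2
        self.sigma_e2 = sigma_e2
        self.update_varcomps = update_varcomps
        self.tol = tol
        self.max_iter = max_iter
        kin = ws.kin
        if kin is not None and sigma_e2 > 0:
            self._w = 1.0 / (sigma_e2 + max(sigma_g2, 0.0) * kin.d)
            wX = self._w[:, None] * ws.UtX
            self._s11 = float(np.sum(self._w * ws.Ut1**2))
            self._s1x = ws.Ut1 @ wX
            self._xwx = np.einsum("ij,ij->j", ws.UtX, wX)
        else:
            self._w = None

    def init_beta(self, y: np.ndarray) -> np.ndarray:
        """Per-SNP GLS effects of y (intercept + SNP, V fixed) — the same
        estimates the mixed-model scan produces for the observed trait."""
        if self._w is None:
            return _marginal_beta(y, self.ws.X)
        kin = self.ws.kin
        yw = self._w * (kin.U.T @ y)
        s1y = float(self.ws.Ut1 @ yw)
        xwy = self.ws.UtX.T @ yw
        det = self._s11 * self._xwx - self._s1x**2
        det = np.where(np.abs(det) < 1e-300, 1.0, det)
        return (self._s11 * xwy - self._s1x * s1y) / det

    def __call__(self, y_perm: np.ndarray) -> tuple[float, bool]:
        fit = _em_fit(
            y_perm,
            self.ws,
            self.priors,
            self.init_beta(y_perm),
            self.sigma_g2,
            self.sigma_e2,
            fix_lambda=False,
            lambda_init=1.0,
            update_varcomps=self.update_varcomps,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        return float(fit.h2.max()) if len(fit.h2) else 0.0, fit.converged


def one_permutation_max_h2(
    y: np.ndarray,
    X: np.ndarray,
    A: RelationshipMatrix | np.ndarray | KinshipFactor | None,
    priors: LassoPriors,
    perm_seed: int,
    sigma_g2: float | None = None,
    sigma_e2: float | None = None,
    update_varcomps: bool = False,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> float:
    """Shuffle y, refit the multi-SNP model, return max_j h_j^2.

    Deterministic given ``perm_seed``.  A non-convergent refit still returns
    its last-iterate maximum (a warning is raised by the fitter).
    """
    y = np.asarray(y, dtype=float)
    kin = None
    if A is not None:
        kin = A if isinstance(A, KinshipFactor) else KinshipFactor(A)
    ws = _Workspace(np.asarray(X, dtype=float), kin)
    sg2, se2 = _init_sigmas(y, kin, sigma_g2, sigma_e2)
    fitter = _PermFitter(ws, priors, sg2, se2, update_varcomps, tol, max_iter)
    rng = np.random.default_rng(perm_seed)
    y_perm = y[rng.permutation(len(y))]
    value, _ = fitter(y_perm)
    return value


def _init_sigmas(
    y: np.ndarray,
    kin: KinshipFactor | None,
    sigma_g2: float | None,
    sigma_e2: float | None,
) -> tuple[float, float]:
    if sigma_g2 is not None and sigma_e2 is not None:
        return float(sigma_g2), float(sigma_e2)
    vy = float(np.var(y))
    if vy <= 0:
        return 0.0, 1.0
    if kin is not None:
        from .scan import estimate_varcomps_null

        vc = estimate_varcomps_null(y, kin.U @ (kin.d[:, None] * kin.U.T))
        return (
            vc.sigma_g2 if sigma_g2 is None else float(sigma_g2),
            vc.sigma_e2 if sigma_e2 is None else float(sigma_e2),
        )
    return (0.0 if sigma_g2 is None else float(sigma_g2),
            vy if sigma_e2 is None else float(sigma_e2))


def permutation_null(
    y: np.ndarray,
    X: np.ndarray,
    A: RelationshipMatrix | np.ndarray | KinshipFactor | None,
    priors: LassoPriors = LassoPriors(),
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    sigma_g2: float | None = None,
    sigma_e2: float | None = None,
    update_varcomps: bool = False,
    tol: float = 1e-6,
    max_iter: int = 1000,
    fitter: Callable[[np.ndarray], tuple[float, bool]] | None = None,
) -> PermutationNull:
    """Permutation null distribution of max_j h_j^2 and its threshold.

    ``fitter`` (mapping a permuted phenotype to ``(max_h2, converged)``)
    exists for testing with a stubbed model; by default the real EM-LASSO is
    refit, sharing the kinship factor and design cross-products across all
    ``n_perm`` permutations.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a usable 95% quantile")
    y = np.asarray(y, dtype=float)
    kin = None
    if A is not None:
        kin = A if isinstance(A, KinshipFactor) else KinshipFactor(A)
    ws = _Workspace(np.asarray(X, dtype=float), kin)
    sg2, se2 = _init_sigmas(y, kin, sigma_g2, sigma_e2)
    if fitter is None:
        fitter = _PermFitter(ws, priors, sg2, se2, update_varcomps, tol, max_iter)
    master = np.random.default_rng(seed)
    perm_seeds = master.integers(0, 2**31 - 1, size=n_perm)
    max_h2 = np.empty(n_perm)
    n_bad = 0
    for k in range(n_perm):
        rng = np.random.default_rng(int(perm_seeds[k]))
        y_perm = y[rng.permutation(len(y))]
        value, ok = fitter(y_perm)
        max_h2[k] = value
        if not ok:
            n_bad += 1
    return PermutationNull(
        max_h2=max_h2,
        alpha=alpha,
        threshold=threshold_from_max(max_h2, alpha),
        seed=seed,
        n_perm=n_perm,
        n_not_converged=n_bad,
    )


def declare_significant(fit, null: PermutationNull) -> np.ndarray:
    """Indices of SNPs with h_j^2 strictly above the threshold, ordered by
    descending heritability."""
    h2 = np.asarray(fit.h2 if hasattr(fit, "h2") else fit, dtype=float)
    hits = np.flatnonzero(h2 > null.threshold)
    return hits[np.argsort(-h2[hits], kind="stable")]
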