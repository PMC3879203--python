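"""Additive (numerator) relationship matrix from a pedigree.

A_ij is twice the kinship coefficient between individuals i and j; the
diagonal is 1 + F_i where F_i is the inbreeding coefficient.  Built by the
tabular (recursive) method, which requires parents to precede offspring —
:func:`build_A` sorts the pedigree itself, so input order does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .pedigree import Pedigree, parent_indices, sort_pedigree


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix A with its individual ordering."""

    ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.A.shape != (n, n):
            raise ValueError("A shape does not match id count")

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        """Rows/columns of A for the given individuals, in the given order.

        The model only needs A among phenotyped individuals; marginalising
        ancestors out of a multivariate normal is exactly sub-matrix
        extraction.
        """
        index = {i: k for k, i in enumerate(self.ids)}
        try:
            pos = np.array([index[i] for i in ids])
        except KeyError as e:
            raise KeyError(f"individual {e.args[0]!r} not in relationship matrix") from e
        return RelationshipMatrix(list(ids), self.A[np.ix_(pos, pos)])

    def cholesky(self, jitter: float = 1e-8) -> np.ndarray:
        """Lower Cholesky factor of A, with at most ``jitter`` added to the
        diagonal to absorb round-off; raises if A is materially non-PSD."""
        try:
            return np.linalg.cholesky(self.A)
        except np.linalg.LinAlgError:
            try:
                return np.linalg.cholesky(self.A + jitter * np.eye(len(self.ids)))
            except np.linalg.LinAlgError as e:
                raise ValueError("relationship matrix is not positive semidefinite") from e


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Tabular method:  A_ii = 1 + 0.5*A_{sire,dam};  A_ij = 0.5*(A_{j,sire(i)} + A_{j,dam(i)}).

    Unknown parents contribute nothing (founders are unrelated and
    non-inbred).  The result is returned in topological (parents-first)
    order; use :meth:`RelationshipMatrix.subset` to realign.
    """
    ped = sort_pedigree(ped)
    sire, dam = parent_indices(ped)
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0:
            A[i, :i] = 0.5 * A[s, :i]
            A[i, i] = 1.0
        elif d >= 0:
            A[i, :i] = 0.5 * A[d, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return RelationshipMatrix(list(ped.ids), A)


def inbreeding(R: RelationshipMatrix) -> np.ndarray:
    """Inbreeding coefficients F_i = A_ii - 1."""
    return np.diag(R.A) - 1.0


def inverse(R: RelationshipMatrix, jitter: float = 1e-8) -> np.ndarray:
    """Dense A^-1 via Cholesky (desk scale; Henderson's sparse rules not needed)."""
    L = R.cholesky(jitter)
    return scipy.linalg.cho_solve((L, True), np.eye(len(R.ids)))
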