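"""The fitted robust-PCA model container and shared linear algebra."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RPCAModel", "reduce_svd", "select_k"]


@dataclass
class RPCAModel:
    """A fitted (robust) PCA model.

    Attributes
    ----------
    center : (p,) robust center of the data.
    loadings : (p, k) column-orthonormal loading matrix P.
    eigenvalues : (k,) robust eigenvalues (squared robust scales of the
        scores), sorted descending.
    scores : (n, k) scores T with rows t_i = P.T (x_i - center).
    method : "grid", "hubert" or "classical".
    metadata : fit provenance (scale estimator, seeds, rank, k rule...).
    """

    center: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    method: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        P = self.loadings
        gram = P.T @ P
        if not np.allclose(gram, np.eye(P.shape[1]), atol=1e-8):
            raise ValueError("loadings are not column-orthonormal")
        lam = np.asarray(self.eigenvalues, dtype=float)
        if np.any(lam < -1e-12):
            raise ValueError("eigenvalues must be nonnegative")
        if np.any(np.diff(lam) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")
        self.eigenvalues = np.maximum(lam, 0.0)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    def project(self, X: np.ndarray) -> np.ndarray:
        """Scores of new observations (rows of X) under the fitted model."""
        return (np.atleast_2d(X) - self.center) @ self.loadings


def reduce_svd(Xc: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, int]:
    """Lossless SVD reduction of centered data to its spanned subspace.

    Returns (Z, basis, rank) with Z = Xc @ basis the n x rank coordinates
    and basis the p x rank orthonormal map back to p-space. When p <= n
    the reduction still drops any null directions of the data.
    """
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    thresh = max(tol, s[0] * 1e-12) if s.size and s[0] > 0 else tol
    rank = int(np.sum(s > thresh))
    if rank == 0:
        raise ValueError("degenerate data: all rows identical after centering")
    basis = vt[:rank].T
    return Xc @ basis, basis, rank


def select_k(
    eigenvalues: np.ndarray,
    kmax: int = 10,
    cum_fraction: float = 0.8,
    ratio_min: float = 1e-3,
) -> int:
    """Automatic component-count rule.

    Smallest k whose cumulative eigenvalue fraction reaches
    ``cum_fraction`` while lambda_k / lambda_1 >= ``ratio_min``,
    capped at ``kmax``.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")
    cum = np.cumsum(lam) / lam.sum()
    ratios = lam / lam[0]
    k = 1
    for j in range(lam.size):
        if ratios[j] < ratio_min:
            break
        k = j + 1
        if cum[j] >= cum_fraction:
            break
    return min(k, kmax, lam.size)
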