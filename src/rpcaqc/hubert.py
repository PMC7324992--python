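"""ROBPCA: outlyingness-based robust PCA with an MCD refinement.

The algorithm combines projection pursuit and robust covariance
estimation: Stahel–Donoho outlyingness along directions through pairs
of data points selects an h-subset of least-outlying observations; the
data are projected onto the leading eigenvectors of that subset's
covariance; and FAST-MCD with reweighting re-estimates location and
scatter in the low-dimensional score space.  The composed rotations
yield robust loadings, eigenvalues and scores in the original space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .model import RPCAModel, reduce_svd, select_k
from .robust import fast_mcd, unimcd

__all__ = ["HubertParams", "pca_hubert"]


@dataclass
class HubertParams:
    """Tuning parameters of the ROBPCA fit.

    alpha is the fraction of observations the fit must resist around
    (h ~ ceil(alpha*n) clean core); k is the number of components or
    None for the automatic rule; n_directions_max bounds the number of
    point-pair projection directions (all pairs are used whenever
    C(n,2) fits, which makes fits at small n fully deterministic).
    """

    alpha: float = 0.75
    k: int | None = None
    kmax: int = 10
    crit: float = 0.975
    n_directions_max: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0.5, 1]")
        if self.kmax < 1:
            raise ValueError("kmax must be >= 1")
        if not 0.0 < self.crit < 1.0:
            raise ValueError("crit must lie in (0, 1)")


def _outlyingness(Z: np.ndarray, alpha: float, n_directions_max: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Max over directions of |projection - robust loc| / robust scale.

    Directions run through pairs of data points; zero-scale directions
    (near-duplicate samples) are skipped.
    """
    n = Z.shape[0]
    pairs = list(combinations(range(n), 2))
    if len(pairs) > n_directions_max:
        sel = rng.choice(len(pairs), size=n_directions_max, replace=False)
        pairs = [pairs[i] for i in sel]
    out = np.zeros(n)
    any_valid = False
    for i, j in pairs:
        d = Z[i] - Z[j]
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            continue
        proj = Z @ (d / nrm)
        ls = unimcd(proj, alpha)
        if ls.scale <= 1e-12:
            continue
        any_valid = True
        np.maximum(out, np.abs(proj - ls.location) / ls.scale, out=out)
    if not any_valid:
        raise ValueError("all projection directions are degenerate")
    return out


def pca_hubert(X: np.ndarray, params: HubertParams | None = None) -> RPCAModel:
    """Fit ROBPCA to an n x p data matrix (rows are samples)."""
    if params is None:
        params = HubertParams()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError("pca_hubert needs at least 4 samples")
    rng = np.random.default_rng(params.seed)

    # Stage 1: lossless reduction to the affine span of the data.
    col_mean = X.mean(axis=0)
    Z, basis, rank = reduce_svd(X - col_mean)

    kmax_eff = min(params.kmax, rank, max(1, n // 2))
    if params.k is not None and params.k > kmax_eff:
        raise ValueError(
            f"k={params.k} exceeds the attainable cap {kmax_eff} "
            f"(min of kmax={params.kmax}, rank={rank}, floor(n/2)={n // 2})"
        )

    # Stage 2: outlyingness-based h-subset.
    out = _outlyingness(Z, params.alpha, params.n_directions_max, rng)
    k_for_h = params.k if params.k is not None else kmax_eff
    h = max(int(math.ceil(params.alpha * n)),
            int(math.ceil((n + k_for_h + 1) / 2)))
    h = min(h, n)
    h0_idx = np.sort(np.argsort(out, kind="stable")[:h])

    # Stage 3: eigenstructure of the clean core; pick k; project.
    core = Z[h0_idx]
    core_mean = core.mean(axis=0)
    cov0 = np.cov(core, rowvar=False, ddof=1).reshape(rank, rank)
    evals, evecs = np.linalg.eigh(cov0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if params.k is not None:
        k = params.k
    else:
        k = min(select_k(np.maximum(evals, 0.0), kmax=kmax_eff), kmax_eff)
    E = evecs[:, :k]
    scores0 = (Z - core_mean) @ E  # n x k

    # Stage 4: MCD in the score space, then rotate to the eigenbasis of
    # the reweighted scatter.
    if n > k + 1 and k >= 1:
        fit = fast_mcd(scores0, alpha=params.alpha, seed=int(rng.integers(2**31)))
        lam, R = np.linalg.eigh(fit.scatter)
        order = np.argsort(lam)[::-1]
        lam, R = np.maximum(lam[order], 0.0), R[:, order]
        center_red = core_mean + E @ fit.center
        mcd_meta = fit.metadata | {"mcd_support_size": int(fit.h),
                                   "mcd_singular": fit.singular_fallback}
    else:  # not enough points for an MCD in k dims; use the core moments
        lam = np.maximum(evals[:k], 0.0)
        R = np.eye(k)
        center_red = core_mean
        mcd_meta = {"mcd_skipped": True}

    loadings = basis @ (E @ R)  # p x k, column-orthonormal
    mu = col_mean + basis @ center_red
    scores = (X - mu) @ loadings
    return RPCAModel(
        center=mu,
        loadings=loadings,
        eigenvalues=lam,
        scores=scores,
        method="hubert",
        metadata={
            "alpha": params.alpha,
            "k_rule": "fixed" if params.k is not None else "auto",
            "kmax_effective": kmax_eff,
            "h": h,
            "h0_indices": h0_idx.tolist(),
            "reduced_rank": rank,
            "seed": params.seed,
            "crit": params.crit,
            **mcd_meta,
        },
    )
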