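"""Projection-pursuit robust PCA via angular grid search.

Each component is the direction maximizing a robust scale of the
projected data, found by scanning plane rotations between the current
best direction and each coordinate axis over an iteratively halved
angular bracket.  With the classical standard deviation as scale the
method reduces to ordinary PCA; with MAD or Qn it resists gross
outliers because a robust scale ignores the extreme projections that
drag the variance-maximizing direction.
"""

from __future__ import annotations

import numpy as np

from .model import RPCAModel, reduce_svd
from .robust import l1_median, mad, qn

__all__ = ["pca_grid"]

_SCALES = {
    "mad": mad,
    "qn": qn,
    "sd": lambda v: float(np.std(v, ddof=1)),
}


def pca_grid(
    X: np.ndarray,
    k: int,
    scale: str = "mad",
    n_angles: int = 10,
    n_refinements: int = 10,
    center: str = "median",
) -> RPCAModel:
    """Fit a k-component grid projection-pursuit robust PCA.

    Parameters
    ----------
    X
        n x p data matrix (rows are samples).
    k
        Number of components, ``1 <= k <= min(n - 1, p)``.
    scale
        Robust scale maximized along candidate directions: ``"mad"``
        (default), ``"qn"``, or ``"sd"`` (classical PCA behaviour).
    n_angles
        Candidate angles scanned per axis and sweep.
    n_refinements
        Sweeps; the angular bracket halves after each one.
    center
        ``"median"`` (coordinatewise, default) or ``"l1median"``.

    The search is fully deterministic. When p > n the data are first
    reduced by SVD to their (at most n-dimensional) spanned subspace,
    which is lossless for any projection index evaluated on the data.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("pca_grid needs at least 3 samples")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k must lie in [1, {min(n - 1, p)}], got {k}")
    if scale not in _SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    scale_fn = _SCALES[scale]

    if center == "median":
        mu = np.median(X, axis=0)
    elif center == "l1median":
        mu = l1_median(X)
    else:
        raise ValueError(f"unknown centering {center!r}")
    Xc = X - mu

    Z, basis, rank = reduce_svd(Xc)
    if k > rank:
        raise ValueError(f"k={k} exceeds the reduced rank {rank}")

    directions = np.zeros((rank, k))
    eigenvalues = np.zeros(k)
    # Orthonormal basis of the not-yet-explained subspace.
    comp_basis = np.eye(rank)
    for m in range(k):
        Y = Z @ comp_basis  # n x r_current
        r_cur = Y.shape[1]
        axis_scales = np.array([scale_fn(Y[:, d]) for d in range(r_cur)])
        if np.all(axis_scales <= 0):
            raise ValueError("degenerate data: zero robust scale in all directions")
        a = np.zeros(r_cur)
        a[int(np.argmax(axis_scales))] = 1.0
        best_obj = scale_fn(Y @ a)
        half_width = np.pi / 2
        for _ in range(n_refinements):
            for d in range(r_cur):
                e = np.zeros(r_cur)
                e[d] = 1.0
                thetas = np.linspace(-half_width, half_width, n_angles)
                for theta in thetas:
                    cand = np.cos(theta) * a + np.sin(theta) * e
                    nrm = np.linalg.norm(cand)
                    if nrm < 1e-12:
                        continue
                    cand /= nrm
                    obj = scale_fn(Y @ cand)
                    if obj > best_obj + 1e-15:
                        best_obj = obj
                        a = cand
            half_width /= 2.0
        eigenvalues[m] = best_obj**2
        directions[:, m] = comp_basis @ a
        # Deflate: restrict the search to the orthogonal complement of a.
        if m < k - 1:
            proj = comp_basis - np.outer(comp_basis @ a, a)
            u, s, _ = np.linalg.svd(proj, full_matrices=False)
            comp_basis = u[:, s > 1e-10]

    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    directions = directions[:, order]
    loadings = basis @ directions  # p x k
    scores = Xc @ loadings
    return RPCAModel(
        center=mu,
        loadings=loadings,
        eigenvalues=eigenvalues,
        scores=scores,
        method="grid",
        metadata={
            "scale": scale,
            "n_angles": n_angles,
            "n_refinements": n_refinements,
            "centering": center,
            "reduced_rank": rank,
        },
    )
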