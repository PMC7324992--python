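"""Robust univariate and low-dimensional multivariate estimators.

Building blocks for the robust PCA fits: the median absolute deviation
(MAD), the Qn scale, the univariate minimum covariance determinant
(MCD), the spatial (L1) median, and FAST-MCD with C-steps and a single
reweighting step.  All estimators are location/scale equivariant;
FAST-MCD is affine equivariant up to the randomness of its starts,
which is fully controlled by an explicit seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LocationScale",
    "MCDFit",
    "mad",
    "qn",
    "unimcd",
    "l1_median",
    "fast_mcd",
]


@dataclass(frozen=True)
class LocationScale:
    """A univariate robust location/scale pair."""

    location: float
    scale: float
    estimator: str = "unimcd"

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("scale must be nonnegative")


@dataclass
class MCDFit:
    """Reweighted minimum-covariance-determinant location/scatter.

    ``center``/``scatter`` are the reweighted estimates used downstream;
    the raw (consistency-corrected) h-subset fit is kept alongside for
    diagnostics and testing.
    """

    center: np.ndarray
    scatter: np.ndarray
    support: np.ndarray  # indices of the raw h-subset
    h: int
    raw_center: np.ndarray
    raw_scatter: np.ndarray
    raw_determinant: float
    consistency_corrected: bool = True
    singular_fallback: bool = False
    metadata: dict = field(default_factory=dict)


def mad(x: np.ndarray, c: float = 1.4826) -> float:
    """Median absolute deviation about the median, scaled by ``c``.

    The default ``c = 1.4826`` makes MAD consistent for the standard
    deviation at the Gaussian model.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("mad requires at least one observation")
    return float(c * np.median(np.abs(x - np.median(x))))


# Finite-sample correction factors for Qn (Croux & Rousseeuw 1992).
_QN_SMALL_N = {2: 0.399, 3: 0.994, 4: 0.512, 5: 0.844,
               6: 0.611, 7: 0.857, 8: 0.669, 9: 0.872}


def _qn_correction(n: int) -> float:
    if n <= 9:
        return _QN_SMALL_N[n]
    if n % 2 == 1:
        return n / (n + 1.4)
    return n / (n + 3.8)


def qn(x: np.ndarray) -> float:
    """Qn scale estimator: the k-th order statistic of pairwise distances.

    Qn = d * c_n * {|x_i - x_j| : i < j}_(k) with k = C(h, 2),
    h = floor(n/2) + 1, d = 2.2219 the Gaussian consistency constant and
    c_n a finite-sample correction.  Computed by explicit enumeration of
    the O(n^2) pairwise differences, which is ample at the sample sizes
    this package targets.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("qn requires at least two observations")
    diffs = np.abs(x[:, None] - x[None, :])[np.triu_indices(n, k=1)]
    h = n // 2 + 1
    k = h * (h - 1) // 2
    kth = np.partition(diffs, k - 1)[k - 1]
    return float(2.2219 * _qn_correction(n) * kth)


def _mcd_consistency(alpha_eff: float, k: int) -> float:
    """Fisher consistency factor for the MCD scatter at coverage alpha.

    c = alpha / P(chi2_{k+2} <= q_alpha) with q_alpha the chi2_k quantile
    at alpha; multiplies the h-subset covariance.
    """
    if alpha_eff >= 1.0:
        return 1.0
    q = stats.chi2.ppf(alpha_eff, df=k)
    denom = stats.chi2.cdf(q, df=k + 2)
    return alpha_eff / denom


def unimcd(x: np.ndarray, alpha: float = 0.75) -> LocationScale:
    """Univariate MCD: mean/sd of the minimal-variance h-subset.

    For sorted data the optimal h-subset is always a contiguous window,
    so all n - h + 1 windows are scanned.  The scale carries the Fisher
    consistency factor for coverage h/n; ties are broken in favour of
    the earliest window.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("unimcd requires at least two observations")
    if not 0.5 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0.5, 1]")
    h = int(math.ceil(alpha * n))
    if h < 2:
        raise ValueError("h = ceil(alpha*n) must be at least 2")
    xs = np.sort(x)
    # Rolling sums over contiguous windows of length h.
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csum2 = np.concatenate([[0.0], np.cumsum(xs**2)])
    win_sum = csum[h:] - csum[:-h]
    win_sum2 = csum2[h:] - csum2[:-h]
    # Sum of squared deviations per window (clipped against roundoff).
    ss = np.maximum(win_sum2 - win_sum**2 / h, 0.0)
    best = int(np.argmin(ss))
    loc = win_sum[best] / h
    var = ss[best] / (h - 1) if h > 1 else 0.0
    scale = math.sqrt(var * _mcd_consistency(h / n, 1))
    return LocationScale(location=float(loc), scale=float(scale))


def l1_median(X: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Spatial median via the modified Weiszfeld iteration.

    Minimizes sum_i ||x_i - m||_2; iterates that land on a data point
    are handled with the Vardi–Zhang correction.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if n == 0:
        raise ValueError("empty input")
    if n == 1:
        return X[0].copy()
    m = np.median(X, axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(X - m, axis=1)
        at_point = d < tol
        if at_point.any():
            # Vardi-Zhang: check optimality at the coinciding data point.
            others = ~at_point
            if not others.any():
                return m
            w = 1.0 / d[others]
            r_vec = ((X[others] - m) * w[:, None]).sum(axis=0)
            eta = float(at_point.sum())
            r = np.linalg.norm(r_vec)
            if r <= eta:
                return m
            m_new = m + max(0.0, 1.0 - eta / r) * r_vec / w.sum()
        else:
            w = 1.0 / d
            m_new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(m_new - m) < tol * (1.0 + np.linalg.norm(m)):
            return m_new
        m = m_new
    raise RuntimeError(
        f"l1_median did not converge in {max_iter} iterations; last iterate {m}"
    )


def _cov_of(Y: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = Y[idx]
    return sub.mean(axis=0), np.cov(sub, rowvar=False, ddof=1).reshape(
        Y.shape[1], Y.shape[1]
    )


def _safe_inv(S: np.ndarray, ridge_flag: list) -> np.ndarray:
    k = S.shape[0]
    try:
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0 or not np.isfinite(logdet):
            raise np.linalg.LinAlgError
        return np.linalg.inv(S)
    except np.linalg.LinAlgError:
        ridge_flag.append(True)
        S_r = S + 1e-8 * (np.trace(S) / k + 1.0) * np.eye(k)
        return np.linalg.inv(S_r)


def _c_steps(
    Y: np.ndarray, center: np.ndarray, scatter: np.ndarray, h: int,
    n_steps: int, tol: float, ridge_flag: list,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Iterate C-steps; determinant of the fitted scatter never increases."""
    n = Y.shape[0]
    prev_logdet = np.inf
    idx = None
    for _ in range(n_steps):
        Sinv = _safe_inv(scatter, ridge_flag)
        diff = Y - center
        d2 = np.einsum("ij,jk,ik->i", diff, Sinv, diff)
        idx = np.argpartition(d2, h - 1)[:h]
        center, scatter = _cov_of(Y, idx)
        sign, logdet = np.linalg.slogdet(scatter)
        if sign <= 0:
            logdet = -np.inf
        if prev_logdet - logdet < tol:
            prev_logdet = logdet
            break
        prev_logdet = logdet
    assert idx is not None
    return center, scatter, np.sort(idx), prev_logdet


def fast_mcd(
    Y: np.ndarray,
    alpha: float = 0.75,
    seed: int = 0,
    n_starts: int = 500,
    n_initial_csteps: int = 2,
    n_best: int = 10,
    tol: float = 1e-12,
    reweight_crit: float = 0.975,
) -> MCDFit:
    """FAST-MCD for small n and small dimension k.

    Random (k+1)-point elemental starts are refined with ``n_initial_csteps``
    C-steps; the ``n_best`` candidates with smallest determinant are iterated
    to convergence (tolerance on the log-determinant).  The raw h-subset fit
    is consistency corrected, then a single reweighting step with the
    chi2_k(``reweight_crit``) cutoff yields the returned center/scatter.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    n, k = Y.shape
    if n <= k + 1:
        raise ValueError(f"need n > k+1 observations (n={n}, k={k})")
    if not 0.5 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0.5, 1]")
    h = int(math.ceil(alpha * n))
    h = max(h, k + 1)
    ridge_flag: list = []

    if h >= n:
        center, scatter = _cov_of(Y, np.arange(n))
        sign, logdet = np.linalg.slogdet(scatter)
        det = math.exp(logdet) if sign > 0 else 0.0
        return MCDFit(
            center=center, scatter=scatter, support=np.arange(n), h=n,
            raw_center=center, raw_scatter=scatter, raw_determinant=det,
            metadata={"alpha": alpha, "n_starts": 0, "classical": True},
        )

    rng = np.random.default_rng(seed)
    n_elemental = math.comb(n, k + 1)
    if n_elemental <= n_starts:
        # small n: enumerate every elemental start (deterministic)
        from itertools import combinations

        starts = [np.array(c) for c in combinations(range(n), k + 1)]
    else:
        starts = [rng.choice(n, size=k + 1, replace=False)
                  for _ in range(n_starts)]
    candidates = []
    for elem in starts:
        center, scatter = _cov_of(Y, elem)
        if np.linalg.matrix_rank(scatter) < k:
            # grow a degenerate elemental set
            extra = rng.choice(n, size=min(n, 2 * (k + 1)), replace=False)
            center, scatter = _cov_of(Y, extra)
        center, scatter, idx, logdet = _c_steps(
            Y, center, scatter, h, n_initial_csteps, tol, ridge_flag
        )
        candidates.append((logdet, center, scatter))
    candidates.sort(key=lambda t: t[0])

    best_logdet = np.inf
    best = None
    for logdet0, center, scatter in candidates[:n_best]:
        center, scatter, idx, logdet = _c_steps(
            Y, center, scatter, h, 100, tol, ridge_flag
        )
        if logdet < best_logdet:
            best_logdet = logdet
            best = (center, scatter, idx)
    assert best is not None
    raw_center, raw_scatter, support = best
    raw_det = float(np.linalg.det(raw_scatter))

    c_raw = _mcd_consistency(h / n, k)
    raw_scatter_c = raw_scatter * c_raw

    # One reweighting step at the chi-square cutoff.
    Sinv = _safe_inv(raw_scatter_c, ridge_flag)
    diff = Y - raw_center
    d2 = np.einsum("ij,jk,ik->i", diff, Sinv, diff)
    cutoff = stats.chi2.ppf(reweight_crit, df=k)
    w = d2 <= cutoff
    if w.sum() < k + 1:
        w = np.zeros(n, bool)
        w[support] = True
    center, scatter = _cov_of(Y, np.flatnonzero(w))
    c_rew = _mcd_consistency(float(w.mean()), k)
    scatter = scatter * c_rew

    if np.linalg.matrix_rank(scatter) < k:
        scatter = scatter + 1e-8 * (np.trace(scatter) / k + 1.0) * np.eye(k)
        ridge_flag.append(True)
    if ridge_flag:
        warnings.warn("fast_mcd encountered a singular scatter; ridge applied",
                      RuntimeWarning, stacklevel=2)
    return MCDFit(
        center=center,
        scatter=scatter,
        support=support,
        h=h,
        raw_center=raw_center,
        raw_scatter=raw_scatter_c,
        raw_determinant=raw_det,
        singular_fallback=bool(ridge_flag),
        metadata={
            "alpha": alpha,
            "seed": seed,
            "n_starts": n_starts,
            "consistency_raw": c_raw,
            "consistency_reweight": c_rew,
            "n_reweighted": int(w.sum()),
        },
    )
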