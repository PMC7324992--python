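"""Score/orthogonal distances, cutoffs and the four-way outlier map.

Every observation is placed in a plane of score distance (SD, robust
Mahalanobis distance within the fitted PCA subspace) against orthogonal
distance (OD, Euclidean distance to that subspace).  Cutoff lines with
a configurable exceedance probability (default 2.5%, crit = 0.975)
partition the plane into regular observations, good leverage points,
orthogonal outliers and bad leverage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import RPCAModel
from .robust import unimcd

__all__ = [
    "OutlierDiagnostics",
    "score_distance",
    "orthogonal_distance",
    "compute_cutoffs",
    "classify",
    "compute_diagnostics",
]

CATEGORIES = ("regular", "good_leverage", "orthogonal_outlier", "bad_leverage")


@dataclass
class OutlierDiagnostics:
    """Per-sample outlier-map diagnostics for one fitted model."""

    sd: np.ndarray
    od: np.ndarray
    c_sd: float
    c_od: float
    category: list[str]
    is_outlier: np.ndarray
    crit: float = 0.975
    od_informative: bool = True
    sample_ids: list[str] | None = None
    metadata: dict = field(default_factory=dict)


def score_distance(model: RPCAModel, scores: np.ndarray | None = None) -> np.ndarray:
    """SD_i = sqrt(sum_j t_ij^2 / lambda_j) for each observation."""
    T = model.scores if scores is None else np.atleast_2d(scores)
    lam = model.eigenvalues
    if np.any(lam <= 0):
        raise ValueError("degenerate eigenvalue: all lambda_j must be positive")
    return np.sqrt(np.sum(T**2 / lam, axis=1))


def orthogonal_distance(model: RPCAModel, X: np.ndarray) -> np.ndarray:
    """OD_i = || x_i - mu - P t_i ||_2 for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.p:
        raise ValueError(f"dimension mismatch: model p={model.p}, data p={X.shape[1]}")
    Xc = X - model.center
    resid = Xc - (Xc @ model.loadings) @ model.loadings.T
    return np.linalg.norm(resid, axis=1)


def compute_cutoffs(
    model: RPCAModel,
    od: np.ndarray,
    crit: float = 0.975,
    od_alpha: float = 0.75,
) -> tuple[float, float, bool]:
    """Cutoffs with exceedance probability 1 - crit on each axis.

    c_sd is the chi-square quantile root for k degrees of freedom.  For
    OD the Wilson–Hilferty approximation is used: od^(2/3) is treated
    as Gaussian with robust (univariate MCD) location m and scale s, and
    c_od = (m + s z_crit)^(3/2).  When the model spans the whole data
    space every OD is ~0; c_od is then 0 and OD is uninformative.
    """
    if not 0.0 < crit < 1.0:
        raise ValueError("crit must lie in (0, 1)")
    c_sd = float(np.sqrt(stats.chi2.ppf(crit, df=model.k)))
    od = np.asarray(od, dtype=float)
    od_scale = float(np.max(od)) if od.size else 0.0
    if od_scale <= 1e-10 * max(1.0, float(np.linalg.norm(model.center))):
        return c_sd, 0.0, False
    ls = unimcd(od ** (2.0 / 3.0), alpha=od_alpha)
    z = stats.norm.ppf(crit)
    c_od = float(max(ls.location + ls.scale * z, 0.0) ** 1.5)
    return c_sd, c_od, True


def classify(
    sd: np.ndarray,
    od: np.ndarray,
    c_sd: float,
    c_od: float,
    od_informative: bool = True,
    policy: str = "any",
) -> tuple[list[str], np.ndarray]:
    """Quadrant assignment by strict exceedance.

    regular: sd <= c_sd and od <= c_od; good_leverage: sd > c_sd only;
    orthogonal_outlier: od > c_od only; bad_leverage: both.  Points
    exactly on a cutoff are regular.  policy "any" flags every
    non-regular point; "od-only" demotes good-leverage points.
    """
    if policy not in ("any", "od-only"):
        raise ValueError(f"unknown outlier policy {policy!r}")
    high_sd = np.asarray(sd) > c_sd
    high_od = (np.asarray(od) > c_od) if od_informative else np.zeros(len(sd), bool)
    cats: list[str] = []
    for hs, ho in zip(high_sd, high_od):
        if hs and ho:
            cats.append("bad_leverage")
        elif hs:
            cats.append("good_leverage")
        elif ho:
            cats.append("orthogonal_outlier")
        else:
            cats.append("regular")
    if policy == "any":
        flags = np.array([c != "regular" for c in cats])
    else:
        flags = np.array([c in ("orthogonal_outlier", "bad_leverage") for c in cats])
    return cats, flags


def compute_diagnostics(
    model: RPCAModel,
    X: np.ndarray,
    crit: float = 0.975,
    policy: str = "any",
    sample_ids: list[str] | None = None,
) -> OutlierDiagnostics:
    """Full outlier-map diagnostics of the fitting data X under model."""
    sd = score_distance(model)
    od = orthogonal_distance(model, X)
    c_sd, c_od, od_informative = compute_cutoffs(model, od, crit=crit)
    cats, flags = classify(sd, od, c_sd, c_od, od_informative, policy=policy)
    return OutlierDiagnostics(
        sd=sd,
        od=od,
        c_sd=c_sd,
        c_od=c_od,
        category=cats,
        is_outlier=flags,
        crit=crit,
        od_informative=od_informative,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
        metadata={"method": model.method, "k": model.k, "policy": policy},
    )


def plot_outlier_map(diag: OutlierDiagnostics, ax=None, annotate: bool = True):
    """Scatter of SD (x) vs OD (y) with cutoff lines. Requires matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = {True: "crimson", False: "steelblue"}
    for i in range(len(diag.sd)):
        ax.scatter(diag.sd[i], diag.od[i], c=colors[bool(diag.is_outlier[i])], s=25)
        if annotate and diag.sample_ids is not None:
            ax.annotate(diag.sample_ids[i], (diag.sd[i], diag.od[i]),
                        fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.axvline(diag.c_sd, ls="--", lw=0.8, c="gray")
    if diag.od_informative:
        ax.axhline(diag.c_od, ls="--", lw=0.8, c="gray")
    ax.set_xlabel("score distance")
    ax.set_ylabel("orthogonal distance")
    return ax
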