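"""Gene filtering, size factors, and variance-stabilizing transforms.

The robust PCA consumes a samples x genes matrix of transformed
expression values.  This module provides the standard preprocessing:
removal of low-count genes, median-of-ratios size factors to correct
sequencing depth, and three transforms — plain log2, an
asinh-based variance-stabilizing transform (vst_approx) with a single
moment-estimated common dispersion, and a shrinkage-based regularized
log (rlog_approx) that pulls noisy low-information genes toward their
across-sample mean, the property that makes rlog the preferred input
when hunting outlier samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import CountMatrix

__all__ = [
    "SizeFactors",
    "TransformedMatrix",
    "filter_low_counts",
    "estimate_size_factors",
    "transform",
]

LOG2 = math.log(2.0)


@dataclass
class SizeFactors:
    """Per-sample depth-normalization factors, geometric mean 1."""

    factors: np.ndarray
    sample_ids: list[str]
    fallback_used: bool = False

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("size factors must be positive")
        if len(self.sample_ids) != self.factors.size:
            raise ValueError("one factor per sample required")


@dataclass
class TransformedMatrix:
    """Samples x genes real matrix fed to the PCA (n rows, p columns)."""

    values: np.ndarray  # n x p
    sample_ids: list[str]
    gene_ids: list[str]
    method: str
    groups: list[str] | None = None
    weights: np.ndarray | None = None  # per-gene rlog shrinkage weights
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.gene_ids) != p:
            raise ValueError("id lists must match matrix dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("transformed values must be finite")


def filter_low_counts(
    counts: CountMatrix, min_total: int = 10, mode: str = "sum"
) -> CountMatrix:
    """Drop genes with insufficient counts.

    mode "sum" (default) removes genes whose summed count across all
    samples is below ``min_total``; mode "each" removes genes where
    every individual sample is below ``min_total``.  Gene order and the
    sample set are preserved.
    """
    if mode == "sum":
        keep = counts.counts.sum(axis=1) >= min_total
    elif mode == "each":
        keep = (counts.counts >= min_total).any(axis=1)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    if not keep.any():
        raise ValueError("all genes removed by the low-count filter")
    idx = np.flatnonzero(keep)
    return CountMatrix(
        counts.counts[idx],
        [counts.gene_ids[i] for i in idx],
        list(counts.sample_ids),
        list(counts.groups),
    )


def estimate_size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    s_j = median over reference genes of K_gj / geometric-mean_g(K_g.),
    restricted to genes with strictly positive counts in every sample,
    then rescaled to geometric mean 1.  When no gene is positive
    everywhere (heavily zero-inflated small matrices) the reference set
    falls back to genes positive in >= 90% of samples with zeros
    treated as missing in the median; a warning is emitted.
    """
    K = counts.counts.astype(float)
    g, n = K.shape
    if n < 2:
        raise ValueError("size factors need at least two samples")
    all_pos = np.all(K > 0, axis=1)
    fallback = False
    with np.errstate(divide="ignore"):
        logK = np.where(K > 0, np.log(K), np.nan)
    if all_pos.any():
        log_gm = logK[all_pos].mean(axis=1)
        log_ratios = logK[all_pos] - log_gm[:, None]
        log_s = np.median(log_ratios, axis=0)
    else:
        frac_pos = (K > 0).mean(axis=1)
        ref = frac_pos >= 0.9
        if not ref.any():
            raise ValueError("no reference genes for size-factor estimation")
        fallback = True
        warnings.warn(
            "no gene has positive counts in every sample; "
            "falling back to genes positive in >= 90% of samples",
            RuntimeWarning, stacklevel=2,
        )
        log_gm = np.nanmean(logK[ref], axis=1)
        log_ratios = logK[ref] - log_gm[:, None]
        log_s = np.nanmedian(log_ratios, axis=0)
    log_s = log_s - log_s.mean()  # geometric mean 1
    return SizeFactors(np.exp(log_s), list(counts.sample_ids), fallback)


def _common_dispersion(Q: np.ndarray) -> float:
    """Method-of-moments common NB dispersion on normalized counts.

    Per gene alpha_g = (var - mean) / mean^2; the estimate is the
    median over genes with positive excess variance, floored at 1e-4.
    """
    m = Q.mean(axis=1)
    v = Q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / m**2
    alpha = alpha[np.isfinite(alpha) & (alpha > 0)]
    if alpha.size == 0:
        return 1e-4
    return float(max(np.median(alpha), 1e-4))


def transform(
    counts: CountMatrix,
    factors: SizeFactors | None = None,
    method: str = "rlog_approx",
) -> TransformedMatrix:
    """Transform normalized counts; returns the samples x genes matrix.

    method "log2": y = log2(K/s + 1).
    method "vst_approx": y = 2/(log 2 * sqrt(a)) * asinh(sqrt(a * K/s))
    with a the moment-estimated common dispersion — approximately
    linear in log2 at high counts, variance-flattened at low counts.
    method "rlog_approx": per-gene shrinkage of the log2 values toward
    the gene mean, y_hat = mu_g + w_g (y - mu_g), with
    w_g = v_between / (v_between + v_noise) and v_noise the delta-method
    log2-scale sampling variance (1/mean + a) / log(2)^2.
    """
    aliases = {"log2": "log2", "vst": "vst_approx", "vst_approx": "vst_approx",
               "rlog": "rlog_approx", "rlog_approx": "rlog_approx"}
    if method not in aliases:
        raise ValueError(f"unknown transform method {method!r}")
    method = aliases[method]
    if factors is None:
        factors = estimate_size_factors(counts)
    if list(factors.sample_ids) != list(counts.sample_ids):
        raise ValueError("size factors do not match the count matrix samples")
    Q = counts.counts / factors.factors[None, :]  # genes x samples, normalized

    weights = None
    meta: dict = {}
    if method == "log2":
        Y = np.log2(Q + 1.0)
    elif method == "vst_approx":
        a = _common_dispersion(Q)
        Y = 2.0 / (LOG2 * math.sqrt(a)) * np.arcsinh(np.sqrt(a * Q))
        meta["dispersion"] = a
    else:  # rlog_approx
        a = _common_dispersion(Q)
        Y = np.log2(Q + 1.0)
        mu = Y.mean(axis=1, keepdims=True)
        v_emp = Y.var(axis=1, ddof=1)
        m_bar = np.maximum(Q.mean(axis=1), 1e-8)
        v_noise = (1.0 / m_bar + a) / LOG2**2
        v_between = np.maximum(v_emp - v_noise, 0.0)
        weights = v_between / (v_between + v_noise)
        Y = mu + weights[:, None] * (Y - mu)
        meta["dispersion"] = a

    return TransformedMatrix(
        values=Y.T,
        sample_ids=list(counts.sample_ids),
        gene_ids=list(counts.gene_ids),
        method=method,
        groups=list(counts.groups),
        weights=weights,
        metadata=meta,
    )
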