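"""Negative-binomial RNA-seq count simulator with ground truth.

Emulates a two-group bulk RNA-seq experiment at the count level:
log-normal baseline gene means, a configurable set of truly
differentially expressed (DE) genes with signed log2 fold changes, and
negative-binomial sampling whose dispersion inflates with a sequencing
"noise level".  Outlier samples carry their own DE program — either
fully disjoint from the baseline program (outlierH, a sample from a
different population) or overlapping it 50% with different fold
changes (outlierL, the severe end of the same condition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationConfig",
    "CountMatrix",
    "SimulationTruth",
    "simulate_baseline",
    "simulate_outlier_sample",
    "simulate_control_sample",
    "inject_into",
    "DISPERSION_NOISE_GAIN",
]

# Dispersion inflation per unit of noise_level:
# dispersion = base_dispersion * (1 + DISPERSION_NOISE_GAIN * noise_level).
# The gain of 20 spreads the standard noise sweep {0.005 .. 0.2} over a
# 1x-5x dispersion range, i.e. visibly different sample heterogeneity.
DISPERSION_NOISE_GAIN = 20.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated two-group experiment.

    noise_level plays the role of a sequencing error rate: it inflates
    the negative-binomial dispersion multiplicatively (see
    DISPERSION_NOISE_GAIN) rather than flipping bases, which keeps the
    simulation at the count level.  Fold-change magnitudes are uniform
    in [fc_log2_low, fc_log2_high] log2 units with random sign.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    n_de_genes: int = 500
    fc_log2_low: float = 1.0
    fc_log2_high: float = 2.0
    noise_level: float = 0.005
    base_dispersion: float = 0.1
    mean_log_location: float = 4.0
    mean_log_scale: float = 1.5
    seed: int = 0
    outlier_model: str = "none"

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_replicates", "n_de_genes", "seed"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise ValueError(f"{name} must be an integer, got {v!r}")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must not exceed n_genes")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.base_dispersion < 0:
            raise ValueError("base_dispersion must be >= 0")
        if not 0 < self.fc_log2_low <= self.fc_log2_high:
            raise ValueError("need 0 < fc_log2_low <= fc_log2_high")
        if self.outlier_model not in ("none", "outlierL", "outlierH"):
            raise ValueError(f"unknown outlier model {self.outlier_model!r}")

    @property
    def dispersion(self) -> float:
        return self.base_dispersion * (1.0 + DISPERSION_NOISE_GAIN * self.noise_level)


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample count matrix with identifiers."""

    counts: np.ndarray  # genes x samples, integer
    gene_ids: list[str]
    sample_ids: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        g, s = self.counts.shape
        if len(self.gene_ids) != g or len(self.sample_ids) != s:
            raise ValueError("id lists must match matrix dimensions")
        if len(self.groups) != s:
            raise ValueError("one group label per sample required")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != s:
            raise ValueError("duplicate sample ids")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), list(self.gene_ids),
                           list(self.sample_ids), list(self.groups))


@dataclass
class SimulationTruth:
    """Ground truth of a simulated experiment, for benchmarking."""

    de_genes: dict[str, float]  # gene id -> signed log2 fold change
    outlier_labels: dict[str, bool]  # sample id -> injected-outlier flag
    outlier_de_genes: dict[str, float] = field(default_factory=dict)
    group1_means: np.ndarray | None = None
    gene_ids: list[str] | None = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float
             ) -> np.ndarray:
    """NB(mean, dispersion) with var = mean + dispersion * mean^2.

    dispersion == 0 is the deterministic limit: counts equal the
    rounded means.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return np.rint(mean).astype(np.int64)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p).astype(np.int64)


def simulate_baseline(config: SimulationConfig) -> tuple[CountMatrix, SimulationTruth]:
    """Simulate the two-group baseline experiment.

    Group-1 means are log-normal (natural-log location/scale from the
    config, truncated below at 1); group-2 means multiply the DE genes'
    means by 2^lfc with signed log2 fold changes lfc.  Counts are NB
    with the config's (noise-inflated) dispersion.  Fully reproducible
    from the seed.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    gene_ids = [f"gene_{i:05d}" for i in range(g)]
    base_means = np.maximum(
        rng.lognormal(config.mean_log_location, config.mean_log_scale, size=g), 1.0
    )
    de_idx = rng.choice(g, size=config.n_de_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    mags = rng.uniform(config.fc_log2_low, config.fc_log2_high,
                       size=config.n_de_genes)
    lfc = np.zeros(g)
    lfc[de_idx] = signs * mags

    means_g2 = base_means * np.exp2(lfc)
    nrep = config.n_replicates
    counts = np.empty((g, 2 * nrep), dtype=np.int64)
    for j in range(nrep):
        counts[:, j] = _nb_draw(rng, base_means, config.dispersion)
    for j in range(nrep):
        counts[:, nrep + j] = _nb_draw(rng, means_g2, config.dispersion)

    sample_ids = [f"g1_rep{j + 1}" for j in range(nrep)] + \
                 [f"g2_rep{j + 1}" for j in range(nrep)]
    groups = ["group1"] * nrep + ["group2"] * nrep
    cm = CountMatrix(counts, gene_ids, sample_ids, groups)
    truth = SimulationTruth(
        de_genes={gene_ids[i]: float(lfc[i]) for i in de_idx},
        outlier_labels={s: False for s in sample_ids},
        group1_means=base_means,
        gene_ids=gene_ids,
    )
    return cm, truth


def simulate_outlier_sample(
    config: SimulationConfig,
    truth: SimulationTruth,
    model: str,
    group: str = "group2",
    sample_id: str | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, SimulationTruth]:
    """Draw one outlier sample column with its own DE program.

    outlierH: a DE gene set of the same size fully disjoint from the
    baseline program.  outlierL: a set sharing exactly ceil(n_de/2)
    genes with the baseline program; fold changes are freshly drawn on
    every gene of the outlier program.  Non-program genes keep the
    baseline means of the requested group, so the "outlierness" is
    carried entirely by the DE program.
    """
    if model not in ("outlierL", "outlierH"):
        raise ValueError(f"nothing to inject for model {model!r}")
    if truth.group1_means is None or truth.gene_ids is None:
        raise ValueError("truth must come from simulate_baseline")
    gene_ids = truth.gene_ids
    g = len(gene_ids)
    n_de = config.n_de_genes
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)

    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    base_de = np.array(sorted(gene_pos[gid] for gid in truth.de_genes))
    non_de = np.setdiff1d(np.arange(g), base_de)

    if model == "outlierH":
        if len(non_de) < n_de:
            raise ValueError("not enough non-DE genes for a disjoint program")
        own = rng.choice(non_de, size=n_de, replace=False)
    else:
        n_shared = int(math.ceil(n_de / 2))
        shared = rng.choice(base_de, size=n_shared, replace=False)
        fresh = rng.choice(non_de, size=n_de - n_shared, replace=False)
        own = np.concatenate([shared, fresh])

    signs = rng.choice([-1.0, 1.0], size=n_de)
    mags = rng.uniform(config.fc_log2_low, config.fc_log2_high, size=n_de)
    own_lfc = np.zeros(g)
    own_lfc[own] = signs * mags

    # The outlier's expression program: its own fold changes applied to
    # the group-1 baseline means when it poses as a group-2 sample.
    means = truth.group1_means.copy()
    if group == "group2":
        means = means * np.exp2(own_lfc)
    else:
        # A group-1 outlier deviates on its program genes relative to the
        # group-1 baseline in the same multiplicative way.
        means[own_lfc != 0] = means[own_lfc != 0] * np.exp2(own_lfc[own_lfc != 0])
    column = _nb_draw(rng, means, config.dispersion)

    sid = sample_id or f"{model}_1"
    new_truth = SimulationTruth(
        de_genes=dict(truth.de_genes),
        outlier_labels={**truth.outlier_labels, sid: True},
        outlier_de_genes={gene_ids[i]: float(own_lfc[i]) for i in own},
        group1_means=truth.group1_means,
        gene_ids=gene_ids,
    )
    return column, new_truth


def simulate_control_sample(
    config: SimulationConfig,
    truth: SimulationTruth,
    group: str = "group2",
    seed: int | None = None,
) -> np.ndarray:
    """A negative-control sample: the baseline expression program of the
    requested group redrawn at the config's (possibly elevated) noise
    level.  Such a sample is noisier than its peers but carries no
    distinct DE program and should not be flagged as an outlier.
    """
    if truth.group1_means is None or truth.gene_ids is None:
        raise ValueError("truth must come from simulate_baseline")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    means = truth.group1_means.copy()
    if group == "group2":
        gene_pos = {gid: i for i, gid in enumerate(truth.gene_ids)}
        for gid, lfc in truth.de_genes.items():
            means[gene_pos[gid]] *= 2.0**lfc
    return _nb_draw(rng, means, config.dispersion)


def inject_into(
    baseline: CountMatrix,
    column: np.ndarray,
    sample_id: str,
    group: str,
    gene_ids: list[str] | None = None,
) -> CountMatrix:
    """Append one sample column to the baseline matrix.

    If ``gene_ids`` is given the column is re-aligned to the baseline
    gene order; unknown or missing genes are an alignment error.
    """
    column = np.asarray(column)
    if gene_ids is not None:
        if set(gene_ids) != set(baseline.gene_ids):
            raise ValueError("gene ids of the column do not match the baseline")
        pos = {gid: i for i, gid in enumerate(gene_ids)}
        column = column[[pos[gid] for gid in baseline.gene_ids]]
    if column.shape[0] != baseline.n_genes:
        raise ValueError("column length does not match the baseline gene count")
    if sample_id in baseline.sample_ids:
        raise ValueError(f"duplicate sample id {sample_id!r}")
    return CountMatrix(
        np.column_stack([baseline.counts, column]),
        list(baseline.gene_ids),
        list(baseline.sample_ids) + [sample_id],
        list(baseline.groups) + [group],
    )
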