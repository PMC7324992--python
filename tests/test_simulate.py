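"""Count-simulator tests: truth contracts, determinism, NB moments."""

import math
from dataclasses import replace

import numpy as np
import pytest

from rpcaqc import (
    CountMatrix,
    SimulationConfig,
    inject_into,
    simulate_baseline,
    simulate_control_sample,
    simulate_outlier_sample,
)


class TestConfig:
    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_de_genes=3000, n_genes=2000)
        with pytest.raises(ValueError):
            SimulationConfig(n_replicates=1)
        with pytest.raises(ValueError):
            SimulationConfig(noise_level=-0.1)
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=2000.5)  # type: ignore[arg-type]

    def test_dispersion_inflation_mapping(self):
        cfg = SimulationConfig(noise_level=0.1, base_dispersion=0.1)
        assert cfg.dispersion == pytest.approx(0.1 * (1 + 20 * 0.1))


class TestBaseline:
    def test_default_truth_has_500_de_genes(self):
        _, truth = simulate_baseline(SimulationConfig(seed=1))
        assert len(truth.de_genes) == 500

    def test_shape_and_groups(self, small_config, baseline):
        cm, _ = baseline
        assert cm.counts.shape == (400, 6)
        assert cm.groups == ["group1"] * 3 + ["group2"] * 3

    def test_same_seed_bit_identical(self, small_config):
        a, ta = simulate_baseline(small_config)
        b, tb = simulate_baseline(small_config)
        assert np.array_equal(a.counts, b.counts)
        assert ta.de_genes == tb.de_genes

    def test_zero_dispersion_limit_is_rounded_means(self):
        cfg = SimulationConfig(n_genes=50, n_de_genes=10, noise_level=0.0,
                               base_dispersion=0.0, seed=4)
        cm, truth = simulate_baseline(cfg)
        # group-1 columns identical (deterministic limit)
        assert np.array_equal(cm.counts[:, 0], cm.counts[:, 1])
        assert np.array_equal(cm.counts[:, 3], cm.counts[:, 4])
        # DE genes differ between groups by the rounded fold change
        pos = {g: i for i, g in enumerate(cm.gene_ids)}
        for gid, lfc in truth.de_genes.items():
            g1 = cm.counts[pos[gid], 0]
            g2 = cm.counts[pos[gid], 3]
            if g1 >= 20:  # rounding noise negligible
                assert g2 / g1 == pytest.approx(2.0**lfc, rel=0.1)

    def test_montecarlo_means_match_configuration(self):
        """Per-gene sample mean over 200 replicates within 3 standard
        errors of the configured NB mean."""
        cfg = SimulationConfig(n_genes=30, n_de_genes=5, n_replicates=200,
                               seed=12)
        cm, truth = simulate_baseline(cfg)
        g1 = cm.counts[:, :200].astype(float)
        means = truth.group1_means
        disp = cfg.dispersion
        se = np.sqrt((means + disp * means**2) / 200)
        assert np.all(np.abs(g1.mean(axis=1) - means) < 3.5 * se)

    def test_fold_change_recovered_at_large_n(self):
        cfg = SimulationConfig(n_genes=60, n_de_genes=20, n_replicates=500,
                               seed=3)
        cm, truth = simulate_baseline(cfg)
        pos = {g: i for i, g in enumerate(cm.gene_ids)}
        g1 = cm.counts[:, :500].mean(axis=1)
        g2 = cm.counts[:, 500:].mean(axis=1)
        for gid, lfc in truth.de_genes.items():
            i = pos[gid]
            if g1[i] > 50:
                assert np.log2(g2[i] / g1[i]) == pytest.approx(lfc, abs=0.15)

    def test_noise_level_never_decreases_variance(self):
        """Higher noise_level inflates the realized per-gene variance."""
        lo = SimulationConfig(n_genes=40, n_de_genes=5, n_replicates=300,
                              noise_level=0.005, seed=8)
        hi = replace(lo, noise_level=0.2)
        v_lo = simulate_baseline(lo)[0].counts[:, :300].var(axis=1).mean()
        v_hi = simulate_baseline(hi)[0].counts[:, :300].var(axis=1).mean()
        assert v_hi > v_lo


class TestOutlierSamples:
    def test_outlierL_shares_exactly_half(self, small_config, baseline):
        _, truth = baseline
        cfg = replace(small_config, outlier_model="outlierL")
        _, t2 = simulate_outlier_sample(cfg, truth, "outlierL", seed=5)
        shared = set(t2.outlier_de_genes) & set(truth.de_genes)
        assert len(t2.outlier_de_genes) == small_config.n_de_genes
        assert len(shared) == math.ceil(small_config.n_de_genes / 2)

    def test_outlierH_is_disjoint(self, small_config, baseline):
        _, truth = baseline
        cfg = replace(small_config, outlier_model="outlierH")
        _, t2 = simulate_outlier_sample(cfg, truth, "outlierH", seed=5)
        assert len(t2.outlier_de_genes) == small_config.n_de_genes
        assert not set(t2.outlier_de_genes) & set(truth.de_genes)

    def test_overlap_counts_at_default_size(self):
        cm, truth = simulate_baseline(SimulationConfig(seed=2))
        cfg = SimulationConfig(seed=2, outlier_model="outlierL")
        _, tl = simulate_outlier_sample(cfg, truth, "outlierL", seed=7)
        assert len(set(tl.outlier_de_genes) & set(truth.de_genes)) == 250

    def test_outlierL_fold_changes_differ_on_shared_genes(self, small_config, baseline):
        _, truth = baseline
        cfg = replace(small_config, outlier_model="outlierL")
        _, t2 = simulate_outlier_sample(cfg, truth, "outlierL", seed=5)
        shared = set(t2.outlier_de_genes) & set(truth.de_genes)
        diffs = [abs(t2.outlier_de_genes[g] - truth.de_genes[g]) for g in shared]
        assert np.mean([d > 1e-6 for d in diffs]) > 0.99

    def test_model_none_rejected(self, small_config, baseline):
        _, truth = baseline
        with pytest.raises(ValueError, match="inject"):
            simulate_outlier_sample(small_config, truth, "none")

    def test_fixed_seed_reproducible(self, small_config, baseline):
        _, truth = baseline
        cfg = replace(small_config, outlier_model="outlierH")
        c1, _ = simulate_outlier_sample(cfg, truth, "outlierH", seed=9)
        c2, _ = simulate_outlier_sample(cfg, truth, "outlierH", seed=9)
        assert np.array_equal(c1, c2)

    def test_outlier_labels_updated(self, contaminated):
        cm, truth = contaminated
        assert truth.outlier_labels["outlierH_1"] is True
        assert sum(truth.outlier_labels.values()) == 1

    def test_control_sample_matches_group_means(self, small_config, baseline):
        cm, truth = baseline
        col = simulate_control_sample(small_config, truth, group="group1", seed=3)
        assert col.shape == (small_config.n_genes,)
        assert np.all(col >= 0)


class TestInjectInto:
    def test_seven_sample_matrix(self, contaminated):
        cm, _ = contaminated
        assert cm.n_samples == 7
        assert cm.sample_ids[-1] == "outlierH_1"

    def test_round_trip_recovers_baseline(self, baseline, small_config):
        cm, truth = baseline
        col = simulate_control_sample(small_config, truth, seed=1)
        combined = inject_into(cm, col, "extra", "group2")
        recovered = CountMatrix(
            combined.counts[:, :-1], combined.gene_ids,
            combined.sample_ids[:-1], combined.groups[:-1],
        )
        assert np.array_equal(recovered.counts, cm.counts)
        assert recovered.sample_ids == cm.sample_ids

    def test_permuted_gene_order_realigned(self, baseline, small_config, rng):
        cm, truth = baseline
        col = simulate_control_sample(small_config, truth, seed=1)
        perm = rng.permutation(cm.n_genes)
        combined = inject_into(cm, col[perm], "extra", "group2",
                               gene_ids=[cm.gene_ids[i] for i in perm])
        direct = inject_into(cm, col, "extra", "group2")
        assert np.array_equal(combined.counts, direct.counts)

    def test_gene_id_mismatch_rejected(self, baseline):
        cm, _ = baseline
        with pytest.raises(ValueError, match="gene ids"):
            inject_into(cm, cm.counts[:, 0], "x", "group1",
                        gene_ids=["bogus"] * cm.n_genes)

    def test_duplicate_sample_id_rejected(self, baseline):
        cm, _ = baseline
        with pytest.raises(ValueError, match="duplicate"):
            inject_into(cm, cm.counts[:, 0], cm.sample_ids[0], "group1")
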