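import numpy as np
import pytest

from rpcaqc import (
    SimulationConfig,
    inject_into,
    simulate_baseline,
    simulate_outlier_sample,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulation config for fast pipeline tests."""
    return SimulationConfig(n_genes=400, n_de_genes=100, seed=11)


@pytest.fixture(scope="session")
def baseline(small_config):
    return simulate_baseline(small_config)


@pytest.fixture(scope="session")
def contaminated(small_config, baseline):
    """Baseline plus one injected outlierH sample (7 samples total)."""
    cm, truth = baseline
    from dataclasses import replace

    cfg = replace(small_config, noise_level=0.05, outlier_model="outlierH")
    col, truth2 = simulate_outlier_sample(cfg, truth, "outlierH", seed=99)
    return inject_into(cm, col, "outlierH_1", "group2"), truth2
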