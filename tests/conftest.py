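import numpy as np
import pytest

from pifdawn import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Noise-free planted experiment: group means are exact."""
    cfg = SimulationConfig(n_genes=400, noise_sd_log2=0.0, seed=7)
    matrix, truth = simulate_expression(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def default_bundle():
    """Planted experiment at the study's default noise level."""
    cfg = SimulationConfig(n_genes=2000, seed=1)
    matrix, truth = simulate_expression(cfg)
    return cfg, matrix, truth


def circular_phase_error(estimated: float, planted: float, period: float = 24.0):
    d = abs(estimated - planted) % period
    return min(d, period - d)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
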