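import numpy as np
import pytest

from pleiopath import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def model1_binary():
    """One medium-size dataset under the vertical model SNP -> FA -> SS."""
    cfg = SimulationConfig(
        n_subjects=3000, n_snps=5, n_pleiotropic=2, true_model=1,
        beta_g_m=0.3, beta_g_y=0.1, beta_m_y=0.5,
        outcome_type="binary", seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def model0_binary():
    """Horizontal-pleiotropy dataset: SNP affects FA and SS independently."""
    cfg = SimulationConfig(
        n_subjects=3000, n_snps=5, n_pleiotropic=2, true_model=0,
        beta_g_m=0.3, beta_g_y=0.3, outcome_type="binary", seed=13,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
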