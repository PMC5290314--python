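import numpy as np
import pandas as pd
import pytest

from arpan.simulate import SimulationConfig, make_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Tiny synthetic cohort for fast structural tests."""
    cfg = SimulationConfig(n_genes=50, n_samples=12, n_tfs=6, n_proteins=4, seed=42)
    return make_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-size cohort for statistical checks."""
    cfg = SimulationConfig(n_genes=500, n_samples=60, n_tfs=20, n_proteins=12, seed=7)
    return make_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
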