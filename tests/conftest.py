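import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")

from pi0bench import (SimulationConfig, bum_mixture_pvalues, compute_pvalues,
                      simulate_study, uniform_grid_pvalues)


@pytest.fixture(scope="session")
def uniform_grid_1000():
    return uniform_grid_pvalues(1000)


@pytest.fixture(scope="session")
def bum_sample():
    """5000 p-values from 0.7*Uniform + 0.3*Beta(0.2, 1)."""
    return bum_mixture_pvalues(5000, w=0.7, a=0.2, seed=42)


@pytest.fixture(scope="session")
def null_pvalues():
    """Complete-null study (pi0 = 1, independent genes), M = 10000."""
    cfg = SimulationConfig(M=10_000, pi0=1.0, rho=0.0, seed=11)
    return compute_pvalues(simulate_study(cfg))


@pytest.fixture(scope="session")
def mixed_pvalues():
    """Default-condition study at pi0 = 0.8, rho = 0, M = 2000."""
    cfg = SimulationConfig(M=2000, pi0=0.8, rho=0.0, seed=7)
    return compute_pvalues(simulate_study(cfg))
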