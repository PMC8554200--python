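import numpy as np
import pytest

from hollimap.covariance import SADParams
from hollimap.dynamics import HollingLVParams
from hollimap.likelihood import FitConfig
from hollimap.simulate import default_config, simulate_dataset


@pytest.fixture
def times16():
    """The standard observation grid: 16 time points over 36 hours."""
    return np.linspace(2.25, 36.0, 16)


@pytest.fixture
def theta():
    """A mildly antagonistic parameter set used across tests."""
    return HollingLVParams(0.5, 24.0, -0.01, 0.4, 21.0, -0.02)


@pytest.fixture
def sad_params():
    return SADParams(phi_e=0.5, phi_s=0.3, nu_e=1.0, nu_s=2.0, rho=0.4)


@pytest.fixture
def fast_fit():
    """Optimizer settings matched to the replicate studies: single start,
    coarser integration step."""
    return FitConfig(step=0.1, n_restarts=1, max_cycles=4, tol=1e-3)


@pytest.fixture(scope="session")
def strong_dataset():
    """A small dataset with a high-heritability causal pair: genotype effects
    dominate noise, so localisation and subset behaviour are near-certain."""
    from dataclasses import replace

    cfg = replace(
        default_config(), n_pairs=40, n_markers=6, causal_a=2, causal_b=3,
        h2=0.6, seed=42,
    )
    return simulate_dataset(cfg)
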