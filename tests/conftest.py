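import numpy as np
import pytest

from adassoc.simulate import CountModel, CoverageLaw, SimConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle():
    """A small but realistic simulated study shared across tests."""
    cfg = SimConfig(n_individuals=120, n_variants=25, seed=99,
                    scenario="alternative", phenotype_kind="binary")
    return simulate_study(cfg)


@pytest.fixture
def fixed_coverage_model():
    """Binomial counts at a constant depth of 20 reads."""
    return CountModel(
        coverage_law=CoverageLaw(kind="fixed", mean=20),
        error_rate=0.01,
        overdispersion=None,
    )
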