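import numpy as np
import pytest

from fcbiomarker import CohortSpec, generate_fc_dataset


@pytest.fixture(scope="session")
def separable_spec():
    """Small, strongly separable cohort: 3 injected edges among 435."""
    return CohortSpec(
        n_std=30, n_hc=30, n_regions=30, seed=42,
        discriminative_edges=[(0, 1, -0.6), (2, 5, 0.6), (10, 20, -0.6)],
    )


@pytest.fixture(scope="session")
def separable_dataset(separable_spec):
    ds, records, truth = generate_fc_dataset(separable_spec)
    return ds, records, truth


@pytest.fixture(scope="session")
def tiny_null_spec():
    """No-signal cohort small enough for repeated nested runs."""
    return CohortSpec(n_std=6, n_hc=6, n_regions=8, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
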