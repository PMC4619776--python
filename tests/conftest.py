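import numpy as np
import pytest

import ark16s as a


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_reference():
    """Three distinct random reference sequences with one taxon each."""
    records, taxonomy = a.make_reference(3, length=800, seed=7)
    return records, taxonomy


@pytest.fixture(scope="session")
def clean_sample():
    """Small error-free, chimera-free sample with known composition."""
    cfg = a.SimulationConfig(
        M_taxa=5, ref_length=1200, abundance_law="uniform", depth=600,
        error_rate=0.0, chimera_rate=0.0, seed=11,
    )
    return a.simulate_sample(cfg)


@pytest.fixture(scope="session")
def clean_features(clean_sample):
    return a.featurize(clean_sample.reads, 6)


@pytest.fixture(scope="session")
def clean_ref(clean_sample):
    return a.build_reference(
        clean_sample.reference, clean_sample.taxonomy, 6, mode="whole"
    )


def random_simplex(rng, m, n=None):
    """Random points on the probability simplex."""
    if n is None:
        return rng.dirichlet(np.ones(m))
    return rng.dirichlet(np.ones(m), size=n)
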