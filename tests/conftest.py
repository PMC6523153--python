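import numpy as np
import pytest
from hypothesis import settings

from bfawm.simulate import SimConfig, simulate_all

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_bundle():
    """A tiny simulated input bundle shared by I/O and stage tests."""
    cfg = SimConfig(
        n_chromosomes=2,
        chrom_length_bp=10_000_000,
        n_markers=200,
        n_animals=120,
        n_traits=4,
        h2_per_trait=(0.36, 0.42, 0.35, 0.42),
        n_genes=20,
        n_tfs=4,
        seed=5,
    )
    return simulate_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
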