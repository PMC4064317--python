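import numpy as np
import pytest

from line1mm.simulate import SimulationConfig, simulate_cohort
from line1mm.genome import GenomeManifest


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-sample cohort on the default toy genome, shared across tests."""
    return simulate_cohort(SimulationConfig(seed=42, n_samples=12, n_mbd_samples=3))


@pytest.fixture(scope="session")
def full_cohort():
    """A cohort at the published aCGH size (67 samples)."""
    return simulate_cohort(SimulationConfig(seed=7, n_samples=67, n_mbd_samples=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_manifest():
    return GenomeManifest({"chr1": 1_000_000, "chr2": 600_000, "chrX": 400_000},
                          sex_chroms=frozenset({"chrX"}))
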