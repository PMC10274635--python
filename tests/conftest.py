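import numpy as np
import pytest

from pvskit.synthetic import CohortSpec, PhantomSpec, generate_tube_phantom, simulate_cohort
from pvskit.volume import Volume3D


@pytest.fixture(scope="session")
def small_phantom():
    """A small noise-free phantom shared across tests (seeded)."""
    spec = PhantomSpec(shape=(48, 48, 48), n_tubes=8, seed=42)
    vol, truth = generate_tube_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def cohort_465():
    """One simulated cohort at the study's sample size."""
    return simulate_cohort(CohortSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def constant_volume():
    return Volume3D(np.full((20, 20, 20), 50.0))
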