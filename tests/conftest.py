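import numpy as np
import pytest

from glycodock.energetics import NonbondedParams, PartnerTerms
from glycodock.fixtures import make_toy_complex


@pytest.fixture(scope="session")
def toy3():
    """Short linear (SL) toy complex with a planted bound pose."""
    return make_toy_complex(n_units=3, branched=False, seed=1)


@pytest.fixture(scope="session")
def toy5b():
    """Long branched (LB) toy complex."""
    return make_toy_complex(n_units=5, branched=True, seed=3)


def random_terms(rng: np.random.Generator, n: int, spread: float = 6.0,
                 offset: float = 0.0) -> PartnerTerms:
    """Random small atom cloud with random nonbonded parameters."""
    return PartnerTerms(
        coords=rng.uniform(-spread, spread, size=(n, 3)) + offset,
        epsilon=rng.uniform(0.05, 0.3, size=n),
        sigma=rng.uniform(2.8, 3.6, size=n),
        charge=rng.uniform(-0.5, 0.5, size=n),
        solv=rng.uniform(-0.02, 0.02, size=n),
        radii=np.full(n, 1.7),
    )
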