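import numpy as np
import pytest
from hypothesis import settings

from signedgroups import Partition, SignedNetwork

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def two_species_net() -> SignedNetwork:
    """a helps b, b harms a: one trophic pair, L=2, K=1, Z=2."""
    return SignedNetwork(("a", "b"), np.array([[0, 1], [-1, 0]]))


@pytest.fixture
def three_species_net() -> SignedNetwork:
    """Single link a->b=+1; used for hand-counted block tallies."""
    signs = np.zeros((3, 3), dtype=int)
    signs[0, 1] = 1
    return SignedNetwork(("a", "b", "c"), signs)


def random_signed_network(
    rng: np.random.Generator, n: int, p_zero: float = 0.5
) -> SignedNetwork:
    p_link = (1.0 - p_zero) / 2.0
    signs = rng.choice([-1, 0, 1], size=(n, n), p=[p_link, p_zero, p_link])
    return SignedNetwork(tuple(f"x{i}" for i in range(n)), signs)


def random_partition(rng: np.random.Generator, n: int, max_groups: int) -> Partition:
    return Partition(rng.integers(1, max_groups + 1, size=n))
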