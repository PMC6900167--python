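import numpy as np
import pytest

from timweb import Community, FoodWeb, LinkParams, SpeciesParams, build_initial_community


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_chain_community(a=0.4, e=0.1, K1=5.0, K2=500.0, K3=500.0):
    """Hand-built 3-species chain: 0 (producer) <- 1 <- 2.

    Parameters chosen for a feasible interior equilibrium; B_star is set
    to an arbitrary positive reference vector (tests that need a true
    equilibrium integrate first).
    """
    web = FoodWeb(
        S=3,
        consumers=np.array([1, 2]),
        resources=np.array([0, 1]),
        niche_values=np.array([0.1, 0.5, 0.9]),
        target_C=0.2,
    )
    species = SpeciesParams(
        M=np.array([1.0, 100.0, 10_000.0]),
        r=np.array([1.0, -0.1 * 100.0**-0.25, -0.1 * 10_000.0**-0.25]),
        K=np.array([K1, K2, K3]),
        m=np.zeros(3),
        level=np.array([1, 2, 3]),
    )
    links = LinkParams(
        resource=np.array([0, 1]),
        consumer=np.array([1, 2]),
        a=np.array([a, a / 2]),
        e=np.array([e, e]),
        omega=np.array([1.0, 1.0]),
    )
    return Community(
        web=web, species=species, links=links,
        B_star=np.array([2.0, 1.5, 0.8]),
        original_ids=np.arange(3),
    )


@pytest.fixture
def chain_community():
    return make_chain_community()


@pytest.fixture(scope="session")
def retained_community():
    """One standard retained community (35-species niche web, C=0.14)."""
    com, _ = build_initial_community(35, 0.14, rng=987, community_id=0)
    return com
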