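import numpy as np
import pytest

from excessbayes import (
    FiniteLattice,
    FixtureSpec,
    classify,
    enumerate_lattice,
    make_fixture,
)


@pytest.fixture(scope="session")
def blocks_fixture():
    """The [2,3,9,6] consecutive diagonal blocks over a fully related
    background (N=20)."""
    return make_fixture(FixtureSpec(kind="blocks_with_background", block_sizes=[2, 3, 9, 6]))


@pytest.fixture(scope="session")
def blocks_lattice(blocks_fixture):
    return enumerate_lattice(blocks_fixture)


@pytest.fixture(scope="session")
def blocks_flat(blocks_lattice):
    return FiniteLattice.from_rough(blocks_lattice)


@pytest.fixture(scope="session")
def blocks_report(blocks_flat):
    return classify(blocks_flat)


@pytest.fixture(scope="session")
def small_blocks_fixture():
    """Two 2x2 diagonal blocks over a background (N=4): the smallest fused
    pair of Boolean lattices."""
    return make_fixture(FixtureSpec(kind="blocks_with_background", block_sizes=[2, 2]))


@pytest.fixture(scope="session")
def small_blocks_flat(small_blocks_fixture):
    return FiniteLattice.from_rough(enumerate_lattice(small_blocks_fixture))


@pytest.fixture(scope="session")
def powerset3_flat():
    lat = enumerate_lattice(make_fixture(FixtureSpec(kind="diagonal", n=3)))
    return FiniteLattice.from_rough(lat)


@pytest.fixture(scope="session")
def o6_flat():
    """The hexagon benchmark O6: bottom < a < b < top and bottom < c < d <
    top — an ortholattice that violates the orthomodular law."""
    leq = np.zeros((6, 6), dtype=bool)
    np.fill_diagonal(leq, True)
    bottom, a, b, c, d, top = range(6)
    for lo, hi in [
        (bottom, a), (bottom, b), (bottom, c), (bottom, d), (bottom, top),
        (a, b), (a, top), (b, top), (c, d), (c, top), (d, top),
    ]:
        leq[lo, hi] = True
    return FiniteLattice.from_leq(leq, labels=["0", "a", "b", "c", "d", "1"])


@pytest.fixture(scope="session")
def make_random_relation():
    """Factory fixture for seeded random relations."""
    return random_relation


def random_relation(rng, n_h, n_d, density=0.4):
    """Random binary relation with no empty data rows (so bottom = ∅)."""
    from excessbayes import BinaryRelation
    from excessbayes.probability import data_labels, hyp_labels

    m = rng.random((n_d, n_h)) < density
    for i in range(n_d):
        if not m[i].any():
            m[i, rng.integers(n_h)] = True
    hl, dl = hyp_labels(n_h), data_labels(n_d)
    pairs = {(hl[j], dl[i]) for i, j in zip(*np.nonzero(m))}
    return BinaryRelation(hl, dl, frozenset(pairs))
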