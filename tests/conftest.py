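"""Shared fixtures: small canonical graphs built programmatically."""

from itertools import combinations

import pytest

from rwscomplex import Network


@pytest.fixture
def triangle() -> Network:
    return Network(edges=[("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3() -> Network:
    """Path a - b - c."""
    return Network(edges=[("a", "b"), ("b", "c")])


@pytest.fixture
def star() -> Network:
    """Star with center c and leaves x, y, z."""
    return Network(edges=[("c", "x"), ("c", "y"), ("c", "z")])


def clique(prefix: str, size: int) -> list[tuple[str, str]]:
    names = [f"{prefix}{i}" for i in range(size)]
    return list(combinations(names, 2))


@pytest.fixture
def two_cliques() -> Network:
    """Two disjoint 5-cliques."""
    return Network(edges=clique("x", 5) + clique("y", 5))


@pytest.fixture
def two_cliques_bridged() -> Network:
    """Two 5-cliques joined by a single edge."""
    net = Network(edges=clique("x", 5) + clique("y", 5))
    net.add_edge("x0", "y0")
    return net
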