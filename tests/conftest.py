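"""Shared fixtures: small hand-built networks and posterior assignments."""

import pytest

from sssx.graph import PairGraph
from sssx.sss import Posteriors


@pytest.fixture
def triangle_graph():
    """An isolated unit-weight triangle a-b-c."""
    return PairGraph.from_edges(
        [("a", "b", 1.0), ("a", "c", 1.0), ("b", "c", 1.0)], source="PPI"
    )


@pytest.fixture
def star_graph():
    """Edge a-b with one extra neighbour on each endpoint."""
    return PairGraph.from_edges(
        [("a", "b", 1.0), ("a", "x", 0.5), ("b", "y", 0.7)], source="PPI"
    )


def make_posteriors(assignment):
    """Build a posterior dict from {pair: (sm, lg)}; non = 1 - sm - lg."""
    return {
        pair: Posteriors(sm, lg, 1.0 - sm - lg) for pair, (sm, lg) in assignment.items()
    }


@pytest.fixture
def single_triangle_network():
    """Triangle with a pendant edge, plus its posterior weighting."""
    g = PairGraph.from_edges(
        [("a", "b", 0.9), ("a", "c", 0.8), ("b", "c", 0.8), ("c", "d", 0.4)]
    )
    posteriors = make_posteriors(
        {
            ("a", "b"): (0.9, 0.05),
            ("a", "c"): (0.8, 0.1),
            ("b", "c"): (0.8, 0.1),
            ("c", "d"): (0.1, 0.2),
        }
    )
    return g, posteriors
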