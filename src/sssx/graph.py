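"""Canonical-pair weighted graph container shared by all stages.

Proteins are opaque string identifiers.  Every protein pair is stored in
canonical form — the lexicographically sorted 2-tuple — so that an undirected
edge has exactly one representation throughout the package and all file
output is diff-stable.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping

__all__ = ["canonical_pair", "PairGraph"]

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the canonical (sorted) form of an undirected protein pair.

    Raises ``ValueError`` on self-pairs: an interaction requires two distinct
    proteins.
    """
    if a == b:
        raise ValueError(f"self-pair rejected: {a!r}")
    return (a, b) if a < b else (b, a)


class PairGraph:
    """Undirected graph with a non-negative score on every edge.

    Used both for per-source evidence graphs (PPI / STRING / LIT, where the
    score is the data-source score) and for the reliable network (where the
    score is the Noisy-Or reliability).  Backed by a dict-of-dicts adjacency;
    edges are always keyed canonically.
    """

    def __init__(self, source: str = "") -> None:
        self.source = source
        self._adj: dict[str, dict[str, float]] = {}

    # -- construction --------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]], source: str = "") -> "PairGraph":
        g = cls(source)
        for a, b, w in edges:
            g.add_edge(a, b, w)
        return g

    def add_edge(self, a: str, b: str, score: float) -> None:
        if score < 0:
            raise ValueError(f"negative edge score {score} on ({a}, {b})")
        a, b = canonical_pair(a, b)
        self._adj.setdefault(a, {})[b] = score
        self._adj.setdefault(b, {})[a] = score

    # -- queries -------------------------------------------------------

    def __contains__(self, pair: Pair) -> bool:
        a, b = pair
        return a in self._adj and b in self._adj[a]

    def __len__(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def score(self, a: str, b: str, default: float = 0.0) -> float:
        """Edge score, or *default* when the edge is absent."""
        return self._adj.get(a, {}).get(b, default)

    def neighbors(self, x: str) -> set[str]:
        return set(self._adj.get(x, ()))

    def weighted_degree(self, x: str) -> float:
        return sum(self._adj.get(x, {}).values())

    def proteins(self) -> set[str]:
        return set(self._adj)

    def edges(self) -> Iterator[tuple[Pair, float]]:
        """Iterate (canonical pair, score) in sorted order."""
        for a in sorted(self._adj):
            for b in sorted(self._adj[a]):
                if a < b:
                    yield (a, b), self._adj[a][b]

    def edge_dict(self) -> dict[Pair, float]:
        return {pair: w for pair, w in self.edges()}

    def pair_neighborhood(self, a: str, b: str) -> set[str]:
        """N_{a,b}: union of the two endpoints' neighbours, minus the endpoints."""
        return (self.neighbors(a) | self.neighbors(b)) - {a, b}

    def common_neighbors(self, a: str, b: str) -> set[str]:
        return self.neighbors(a) & self.neighbors(b)

    def triangles(self) -> Iterator[tuple[str, str, str]]:
        """Iterate all triangles as sorted 3-tuples, each exactly once."""
        for (a, b), _ in self.edges():
            for c in sorted(self.common_neighbors(a, b)):
                if c > b:  # a < b < c: emit each triangle once
                    yield (a, b, c)

    @classmethod
    def from_mapping(cls, scores: Mapping[Pair, float], source: str = "") -> "PairGraph":
        g = cls(source)
        for (a, b), w in scores.items():
            g.add_edge(a, b, w)
        return g
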