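"""Per-edge features over the evidence graphs.

Three data sources each provide a scored pair graph: the Noisy-Or-scored PPI
network, STRING functional associations, and literature co-occurrence (LIT,
the Jaccard similarity of two proteins' publication sets).  From each source
graph three topological features are derived for a protein pair (a, b):

DEG
    weighted degree of the pair — the summed scores of edges leaving {a, b}.
SHARED
    shared-neighbour similarity by the iterative AdjustCD function of the
    CMC clustering method, run for two iterations: edge weights are
    recomputed from the weighted common-neighbourhood overlap of the
    previous iteration, with a penalty pulling low-degree proteins toward
    the mean weighted degree.
NBC
    neighbourhood connectivity — the weighted density among the pair's
    neighbours N_{a,b} = (N_a ∪ N_b) \\ {a, b}, with the effective
    neighbourhood size capped by a dampening factor λ.

Together with the three source scores this yields the twelve-feature table
over the reliable network's edges.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from collections.abc import Mapping

import pandas as pd

from .graph import PairGraph

__all__ = [
    "lit_jaccard",
    "lit_graph",
    "degree_feature",
    "nbc_feature",
    "AdjustCD",
    "shared_feature",
    "assemble_feature_table",
    "FEATURE_SOURCES",
]

Pair = tuple[str, str]

FEATURE_SOURCES = ("PPI", "STRING", "LIT")


def lit_jaccard(paper_sets: Mapping[str, set[str]], pair: Pair) -> float:
    """Jaccard similarity of the two proteins' publication sets.

    A protein absent from ``paper_sets`` has an empty set; an empty union
    scores 0.
    """
    a, b = pair
    set_a = paper_sets.get(a, set())
    set_b = paper_sets.get(b, set())
    union = len(set_a | set_b)
    if union == 0:
        return 0.0
    return len(set_a & set_b) / union


def lit_graph(paper_sets: Mapping[str, set[str]]) -> PairGraph:
    """Build the LIT evidence graph of all pairs with nonzero Jaccard score.

    Only pairs sharing at least one publication can score nonzero, so the
    candidate pairs are enumerated through an inverted publication index
    rather than over all protein pairs.
    """
    by_paper: dict[str, list[str]] = defaultdict(list)
    for protein in sorted(paper_sets):
        for paper in sorted(paper_sets[protein]):
            by_paper[paper].append(protein)

    g = PairGraph(source="LIT")
    seen: set[Pair] = set()
    for proteins in by_paper.values():
        for a, b in itertools.combinations(proteins, 2):
            pair = (a, b) if a < b else (b, a)
            if pair not in seen:
                seen.add(pair)
                g.add_edge(*pair, lit_jaccard(paper_sets, pair))
    return g


def degree_feature(graph: PairGraph, pair: Pair) -> float:
    """DEG(a, b): summed scores of edges leaving the pair (the (a,b) edge excluded)."""
    a, b = pair
    deg = graph.weighted_degree(a) + graph.weighted_degree(b)
    return deg - 2.0 * graph.score(a, b)


def nbc_feature(graph: PairGraph, pair: Pair, lam: float = 10.0) -> float:
    """NBC(a, b): weighted density among the pair's neighbourhood N_{a,b}.

    The sum runs over ordered pairs of neighbours (each undirected edge
    counted twice), divided by m(m−1) with m = min(|N_{a,b}|, λ), giving a
    density on the scale of the edge weights.  Neighbourhoods of fewer than
    two proteins score 0.
    """
    if lam < 2:
        raise ValueError(f"dampening factor must be >= 2, got {lam}")
    a, b = pair
    nbhd = graph.pair_neighborhood(a, b)
    if len(nbhd) < 2:
        return 0.0
    total = 0.0
    for x, y in itertools.combinations(sorted(nbhd), 2):
        total += 2.0 * graph.score(x, y)
    m = min(len(nbhd), lam)
    return total / (m * (m - 1))


class AdjustCD:
    """Iterative AdjustCD shared-neighbour scores on one evidence graph.

    Iteration 0 weights are the source scores.  At iteration k the score of
    a pair (u, v) is

        w_k(u, v) = sum_{x in N_u ∩ N_v} (w_{k-1}(u,x) + w_{k-1}(v,x))
                    -----------------------------------------------------
                    λ_u^k + deg_{k-1}(u) + λ_v^k + deg_{k-1}(v)

    where deg_{k-1}(u) = sum_{x in N_u} w_{k-1}(u, x) and the penalty
    λ_u^k = max(0, avg_deg_{k-1} − deg_{k-1}(u)) uses the mean weighted
    degree over all proteins of the graph at the previous iteration.  The
    graph topology (the neighbour sets) is fixed throughout; only edge
    weights are re-estimated.  After fitting, ``score`` evaluates the final
    iteration's formula for any query pair, whether or not it is a graph
    edge.
    """

    def __init__(self, graph: PairGraph, iterations: int = 2) -> None:
        if iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {iterations}")
        self._graph = graph
        # run iterations-1 weight updates on the graph edges; score() then
        # applies the final update to the query pair
        weights = graph.edge_dict()
        for _ in range(iterations - 1):
            self._set_state(weights)
            weights = {pair: self._evaluate(pair) for pair in weights}
        self._set_state(weights)

    def _set_state(self, weights: dict[Pair, float]) -> None:
        self._weights = weights
        deg: dict[str, float] = defaultdict(float)
        for (u, v), w in weights.items():
            deg[u] += w
            deg[v] += w
        self._deg = deg
        n = len(self._graph.proteins())
        self._avg_deg = sum(deg.values()) / n if n else 0.0

    def _weight(self, u: str, v: str) -> float:
        pair = (u, v) if u < v else (v, u)
        return self._weights.get(pair, 0.0)

    def _evaluate(self, pair: Pair) -> float:
        u, v = pair
        common = sorted(self._graph.common_neighbors(u, v))
        num = sum(self._weight(u, x) + self._weight(v, x) for x in common)
        if num == 0.0:
            return 0.0
        deg_u = self._deg.get(u, 0.0)
        deg_v = self._deg.get(v, 0.0)
        lam_u = max(0.0, self._avg_deg - deg_u)
        lam_v = max(0.0, self._avg_deg - deg_v)
        den = lam_u + deg_u + lam_v + deg_v
        return num / den if den > 0 else 0.0

    def score(self, pair: Pair) -> float:
        return self._evaluate(pair)


def shared_feature(graph: PairGraph, pair: Pair, iterations: int = 2) -> float:
    """SHARED(a, b): iterative AdjustCD score after the given iterations."""
    return AdjustCD(graph, iterations).score(pair)


def assemble_feature_table(
    reliable: PairGraph,
    graphs: Mapping[str, PairGraph],
    lam: float = 10.0,
    shared_iterations: int = 2,
) -> pd.DataFrame:
    """Twelve-feature table with one row per reliable-network edge.

    Columns: the three source scores (0 when the edge is absent from a
    source) and DEG / SHARED / NBC per source, computed on each source's
    full graph.  Rows are indexed by the canonical pair and sorted.
    """
    missing = [s for s in FEATURE_SOURCES if s not in graphs]
    if missing:
        raise KeyError(f"missing evidence graphs for sources: {missing}")

    pairs = [pair for pair, _ in reliable.edges()]
    adjustcd = {s: AdjustCD(graphs[s], shared_iterations) for s in FEATURE_SOURCES}

    cols: dict[str, list[float]] = defaultdict(list)
    for pair in pairs:
        for s in FEATURE_SOURCES:
            g = graphs[s]
            cols[s].append(g.score(*pair))
            cols[f"DEG_{s}"].append(degree_feature(g, pair))
            cols[f"SHARED_{s}"].append(adjustcd[s].score(pair))
            cols[f"NBC_{s}"].append(nbc_feature(g, pair, lam))

    index = pd.MultiIndex.from_tuples(pairs, names=["protein_a", "protein_b"])
    order = [f for s in FEATURE_SOURCES for f in (s, f"DEG_{s}", f"SHARED_{s}", f"NBC_{s}")]
    return pd.DataFrame(cols, index=index)[order]
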