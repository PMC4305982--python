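"""Extract: small-complex candidates from the SSS-weighted network.

The small-co-complex posterior P_sm of an edge conflates "is a size-2
complex" with "is part of a size-3 complex".  Extract first disambiguates it
into component scores: the size-2 score of an edge is reduced by the mass of
its incident triangles, and its size-3 score with respect to a particular
triangle (a, b, c) is reduced by the mass of the *other* incident triangles.
These are scores, not probabilities — the subtraction may go negative, and
negative values are clamped to zero.

Candidates are every edge (size 2) and every triangle (size 3) of the
reliable network.  Each is scored by cohesiveness-weighted density: the mean
internal component score times the cohesiveness, i.e. the ratio of internal
component score to internal plus outgoing co-complex weight (P_sm + P_lg of
every edge leaving the cluster).  Averaging over surrounding edges makes the
score robust to a single noisy edge weight, which matters precisely for
clusters with only one or three internal edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping

from .graph import PairGraph
from .sss import Posteriors

__all__ = [
    "ComponentScores",
    "PredictedCluster",
    "disambiguate",
    "cohesiveness2",
    "cohesiveness3",
    "score_clusters",
]

Pair = tuple[str, str]


@dataclass
class ComponentScores:
    """Size-2 and per-triangle size-3 component scores of one edge."""

    pair: Pair
    sm2: float
    sm3: dict[str, float] = field(default_factory=dict)  # third protein -> score


@dataclass(frozen=True)
class PredictedCluster:
    """A candidate small complex with its cohesiveness and final score."""

    members: tuple[str, ...]
    cohesiveness: float
    score: float

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


def disambiguate(
    posteriors: Mapping[Pair, Posteriors], reliable: PairGraph
) -> dict[Pair, ComponentScores]:
    """Decompose each edge's P_sm into size-2 and size-3 component scores.

    P'_sm2(a,b) subtracts, for every common neighbour x, the triangle mass
    P_sm(a,b)·P_sm(a,x)·P_sm(b,x); P'_sm3,abc subtracts the same terms for
    all common neighbours except c.  Negative results are clamped to 0.
    """

    def p_sm(x: str, y: str) -> float:
        return posteriors[(x, y) if x < y else (y, x)].sm

    out: dict[Pair, ComponentScores] = {}
    for (a, b), _ in reliable.edges():
        base = p_sm(a, b)
        tri_mass = {c: base * p_sm(a, c) * p_sm(b, c)
                    for c in sorted(reliable.common_neighbors(a, b))}
        total = sum(tri_mass.values())
        sm2 = max(0.0, base - total)
        sm3 = {c: max(0.0, base - (total - mass)) for c, mass in tri_mass.items()}
        out[(a, b)] = ComponentScores(pair=(a, b), sm2=sm2, sm3=sm3)
    return out


def _outgoing_weight(
    members: tuple[str, ...],
    posteriors: Mapping[Pair, Posteriors],
    reliable: PairGraph,
) -> float:
    """Sum of P_sm + P_lg over reliable edges leaving the member set."""
    inside = set(members)
    total = 0.0
    for x in members:
        for y in sorted(reliable.neighbors(x) - inside):
            p = posteriors[(x, y) if x < y else (y, x)]
            total += p.sm + p.lg
    return total


def cohesiveness2(
    pair: Pair,
    components: Mapping[Pair, ComponentScores],
    posteriors: Mapping[Pair, Posteriors],
    reliable: PairGraph,
) -> float:
    """Coh(a,b): internal component score over internal plus outgoing weight."""
    internal = components[pair].sm2
    outgoing = _outgoing_weight(pair, posteriors, reliable)
    if internal == 0.0 and outgoing == 0.0:
        return 0.0
    return internal / (internal + outgoing)


def cohesiveness3(
    triple: tuple[str, str, str],
    components: Mapping[Pair, ComponentScores],
    posteriors: Mapping[Pair, Posteriors],
    reliable: PairGraph,
) -> float:
    """Coh(a,b,c) over the three size-3 component scores of the triangle."""
    a, b, c = triple
    internal = (
        components[(a, b)].sm3[c]
        + components[(a, c)].sm3[b]
        + components[(b, c)].sm3[a]
    )
    outgoing = _outgoing_weight(triple, posteriors, reliable)
    if internal == 0.0 and outgoing == 0.0:
        return 0.0
    return internal / (internal + outgoing)


def score_clusters(
    posteriors: Mapping[Pair, Posteriors],
    reliable: PairGraph,
    min_score: float = 0.0,
    cohesiveness_weighting: bool = True,
) -> list[PredictedCluster]:
    """Score every edge and triangle; return clusters sorted by score.

    score(a,b) = Coh(a,b) · P'_sm2(a,b);
    score(a,b,c) = Coh(a,b,c) · mean of the three P'_sm3 scores.
    With ``cohesiveness_weighting=False`` the cohesiveness factor is dropped
    and scores are the plain component-score densities.  Ties are broken by
    canonical member order; a triangle and its constituent edges may both
    appear.  Clusters scoring below ``min_score`` (or exactly 0 when
    ``min_score`` is 0) are omitted.
    """
    components = disambiguate(posteriors, reliable)
    clusters: list[PredictedCluster] = []

    for (a, b), _ in reliable.edges():
        coh = cohesiveness2((a, b), components, posteriors, reliable)
        density = components[(a, b)].sm2
        score = coh * density if cohesiveness_weighting else density
        if score > min_score or (min_score > 0 and score == min_score):
            clusters.append(PredictedCluster((a, b), coh, score))

    for a, b, c in reliable.triangles():
        coh = cohesiveness3((a, b, c), components, posteriors, reliable)
        density = (
            components[(a, b)].sm3[c]
            + components[(a, c)].sm3[b]
            + components[(b, c)].sm3[a]
        ) / 3.0
        score = coh * density if cohesiveness_weighting else density
        if score > min_score or (min_score > 0 and score == min_score):
            clusters.append(PredictedCluster((a, b, c), coh, score))

    clusters.sort(key=lambda cl: (-cl.score, cl.members))
    return clusters
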