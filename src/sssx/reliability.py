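"""Noisy-Or reliability scoring of raw PPI evidence.

High-throughput interaction datasets record, for each detected protein pair,
which experimental method found it and in which publication.  Each detection
method *i* is assigned a reliability ``rel_i``: the fraction of its detected
pairs whose proteins are co-localized (share a high-level cellular-component
GO annotation; the co-localization predicate is supplied by the caller).  The
reliability of an interaction (a, b) then combines all its evidence under a
Noisy-Or model:

    reliability(a, b) = 1 - prod_i (1 - rel_i)^(n_i)

over the methods i that detected the pair, where n_i is the number of times
method i detected it.  The network to be weighted downstream keeps only the
top-k pairs by reliability.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from collections.abc import Iterable, Mapping

from .graph import PairGraph, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "EvidenceRecord",
    "deduplicate_evidence",
    "estimate_method_reliability",
    "bin_consolidated_scores",
    "noisy_or_reliability",
    "score_evidence",
    "top_k_filter",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class EvidenceRecord:
    """One detection event: a pair seen by a method in a publication."""

    protein_a: str
    protein_b: str
    method: str
    publication: str
    source: str = ""

    def __post_init__(self) -> None:
        a, b = canonical_pair(self.protein_a, self.protein_b)
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)

    @property
    def pair(self) -> Pair:
        return (self.protein_a, self.protein_b)


def deduplicate_evidence(
    records: Iterable[EvidenceRecord],
    priority_sources: list[str],
) -> list[EvidenceRecord]:
    """Drop duplicate evidence across datasets by publication ID.

    When the same (pair, publication) appears in several source datasets,
    only the record from the highest-priority source is kept, so one
    experiment is never counted twice in the Noisy-Or product.  Records with
    an empty publication ID cannot be matched and are retained with a
    warning.
    """
    records = list(records)
    rank = {s: i for i, s in enumerate(priority_sources)}

    best: dict[tuple[Pair, str], int] = {}
    for rec in records:
        if not rec.publication:
            continue
        key = (rec.pair, rec.publication)
        r = rank.get(rec.source, len(rank))
        if key not in best or r < best[key]:
            best[key] = r

    kept: list[EvidenceRecord] = []
    for rec in records:
        if not rec.publication:
            logger.warning("evidence record without publication ID retained: %s", rec)
            kept.append(rec)
            continue
        if rank.get(rec.source, len(rank)) == best[(rec.pair, rec.publication)]:
            kept.append(rec)
    return kept


def estimate_method_reliability(
    records: Iterable[EvidenceRecord],
    colocalized: Mapping[Pair, bool],
) -> dict[str, float]:
    """Per-method reliability: fraction of distinct detected pairs co-localized.

    Methods that detected no pairs are excluded (with a warning via the
    caller's record set being empty for them, which cannot happen here since
    methods arise from records).
    """
    pairs_by_method: dict[str, set[Pair]] = defaultdict(set)
    for rec in records:
        pairs_by_method[rec.method].add(rec.pair)

    rels: dict[str, float] = {}
    for method in sorted(pairs_by_method):
        pairs = pairs_by_method[method]
        missing = [p for p in pairs if p not in colocalized]
        if missing:
            raise KeyError(
                f"colocalization predicate undefined for {len(missing)} pairs "
                f"detected by method {method!r}, e.g. {missing[0]}"
            )
        rels[method] = sum(colocalized[p] for p in pairs) / len(pairs)
    return rels


def bin_consolidated_scores(pairs: Mapping[Pair, float]) -> list[EvidenceRecord]:
    """Turn pre-scored pairs into pseudo-method evidence by decile binning.

    Scores in [0,1] are assigned to ten equally spaced bins ``bin_0`` …
    ``bin_9`` (left-closed intervals; 1.0 falls in the top bin), each bin
    acting as a separate experimental method whose reliability is estimated
    like any other.
    """
    records = []
    for (a, b) in sorted(pairs):
        s = pairs[(a, b)]
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score {s} for pair ({a}, {b}) outside [0, 1]")
        j = min(int(s * 10), 9)
        records.append(
            EvidenceRecord(a, b, method=f"bin_{j}", publication="", source="consolidated")
        )
    return records


def noisy_or_reliability(
    pair_evidence: Mapping[str, int],
    rels: Mapping[str, float],
    on_missing_method: str = "skip",
) -> float:
    """Noisy-Or combination 1 - prod_i (1 - rel_i)^(n_i) over detecting methods.

    ``pair_evidence`` maps each detecting method to its detection count.
    Methods without an estimated reliability are skipped by default
    (``on_missing_method="error"`` raises instead).
    """
    log_miss = 0.0  # accumulate log(1 - rel_i) * n_i for numerical safety
    for method, n in pair_evidence.items():
        if n < 1:
            raise ValueError(f"evidence count {n} < 1 for method {method!r}")
        if method not in rels:
            if on_missing_method == "skip":
                logger.warning("method %r has no estimated reliability; skipped", method)
                continue
            raise KeyError(f"method {method!r} has no estimated reliability")
        rel = rels[method]
        if rel >= 1.0:
            return 1.0
        log_miss += n * math.log1p(-rel)
    return -math.expm1(log_miss)


def score_evidence(
    records: Iterable[EvidenceRecord],
    rels: Mapping[str, float],
    on_missing_method: str = "skip",
) -> dict[Pair, float]:
    """Score every evidenced pair with its Noisy-Or reliability."""
    counts: dict[Pair, Counter] = defaultdict(Counter)
    for rec in records:
        counts[rec.pair][rec.method] += 1
    return {
        pair: noisy_or_reliability(counts[pair], rels, on_missing_method)
        for pair in sorted(counts)
    }


def top_k_filter(scored_pairs: Mapping[Pair, float], k: int) -> PairGraph:
    """Keep the k highest-reliability edges (all, if fewer exist).

    Ties at the k-th score are broken by canonical pair order so the
    selection is reproducible.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(scored_pairs.items(), key=lambda item: (-item[1], item[0]))
    return PairGraph.from_edges(
        ((a, b, w) for (a, b), w in ranked[:k]), source="PPI"
    )
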