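"""Readers and writers for the package's TSV interchange formats.

All pair-keyed output is written in canonical (sorted-pair) row order so
re-runs diff cleanly.  Formats:

scored pairs      protein_a  protein_b  score
evidence          protein_a  protein_b  method  publication  source
colocalization    protein_a  protein_b  colocalized (0/1)
publication sets  protein    publication
posterior weights protein_a  protein_b  P_sm  P_lg  P_non
clusters          size  member_1  member_2  member_3  cohesiveness  score
complex catalogue one complex per line, tab-separated member IDs (no header)
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd

from .extract import PredictedCluster
from .graph import PairGraph, canonical_pair
from .reliability import EvidenceRecord
from .sss import Posteriors, load_complexes

Pair = tuple[str, str]


def read_scored_pairs(
    path: str | Path, source: str = "", min_score: float | None = None
) -> PairGraph:
    """Read a scored pair TSV into a graph, optionally thresholding (strict >)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    g = PairGraph(source=source)
    for a, b, s in df[["protein_a", "protein_b", "score"]].itertuples(index=False):
        if min_score is None or s > min_score:
            g.add_edge(a, b, float(s))
    return g


def write_scored_pairs(path: str | Path, scores: Mapping[Pair, float] | PairGraph) -> None:
    items = scores.edges() if isinstance(scores, PairGraph) else sorted(scores.items())
    df = pd.DataFrame(
        [(a, b, s) for (a, b), s in items], columns=["protein_a", "protein_b", "score"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_evidence(path: str | Path) -> list[EvidenceRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        EvidenceRecord(r.protein_a, r.protein_b, r.method, r.publication,
                       getattr(r, "source", ""))
        for r in df.itertuples(index=False)
    ]


def read_colocalization(path: str | Path) -> dict[Pair, bool]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    return {
        canonical_pair(r.protein_a, r.protein_b): bool(int(r.colocalized))
        for r in df.itertuples(index=False)
    }


def read_publication_sets(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    sets: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        sets.setdefault(r.protein, set()).add(r.publication)
    return sets


def read_complex_catalogue(path: str | Path) -> list[frozenset[str]]:
    with open(path) as fh:
        return load_complexes(fh)


def write_complex_catalogue(path: str | Path, complexes: Iterable[frozenset[str]]) -> None:
    lines = sorted("\t".join(sorted(cx)) for cx in complexes)
    Path(path).write_text("\n".join(lines) + "\n")


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=["protein_a", "protein_b"])


def write_posteriors(path: str | Path, posteriors: Mapping[Pair, Posteriors]) -> None:
    rows = [
        (a, b, p.sm, p.lg, p.non) for (a, b), p in sorted(posteriors.items())
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "P_sm", "P_lg", "P_non"]).to_csv(
        path, sep="\t", index=False
    )


def read_posteriors(path: str | Path) -> dict[Pair, Posteriors]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    return {
        canonical_pair(r.protein_a, r.protein_b): Posteriors(r.P_sm, r.P_lg, r.P_non)
        for r in df.itertuples(index=False)
    }


def write_clusters(path: str | Path, clusters: Iterable[PredictedCluster]) -> None:
    rows = []
    for cl in clusters:
        members = list(cl.members) + [""] * (3 - cl.size)
        rows.append((cl.size, *members, cl.cohesiveness, cl.score))
    pd.DataFrame(
        rows,
        columns=["size", "member_1", "member_2", "member_3", "cohesiveness", "score"],
    ).to_csv(path, sep="\t", index=False)


def read_clusters(path: str | Path) -> list[PredictedCluster]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={
        "member_1": str, "member_2": str, "member_3": str})
    out = []
    for r in df.itertuples(index=False):
        members = tuple(m for m in (r.member_1, r.member_2, r.member_3) if m)
        out.append(PredictedCluster(members, float(r.cohesiveness), float(r.score)))
    return out
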