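"""Size-specific supervised weighting (SSS) of the reliable PPI network.

Every edge of the reliable network is a data instance with the twelve
source/topology features.  Using a reference complex catalogue, each edge is
labelled ``lg-comp`` (both proteins in the same large complex, size > 3),
``sm-comp`` (both in the same small complex, size 2–3) or ``non-comp``, with
lg-comp taking precedence.  Weighting proceeds in six steps:

1. Fayyad–Irani MDL supervised discretization of each feature; features for
   which no entropy-reducing partition passes the MDL test are removed
   (a built-in feature selection).
2. Maximum-likelihood class-conditional tables P(F = f | class) and class
   priors are estimated by counting.
3. Naive-Bayes posteriors P_sm, P_lg, P_non are computed for every edge.
4. An isolatedness feature ISO = ISO2 + ISO3 is derived from those
   posteriors: the probability mass for the edge being an isolated edge, or
   part of an isolated triangle, in the posterior-weighted network.
5. ISO is itself MDL-discretized and its class-conditional table learned.
6. Posteriors are recomputed with ISO included; these are the final weights.

Small complexes sit in sparse neighbourhoods, so ISO discriminates sm-comp
edges from lg-comp edges even when their data-source scores look alike.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .graph import PairGraph

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSES",
    "Posteriors",
    "load_complexes",
    "label_edges",
    "mdl_discretize",
    "Discretizer",
    "SSSModel",
    "learn_ml_params",
    "naive_bayes_posteriors",
    "iso_feature",
    "sss_weight",
]

Pair = tuple[str, str]

CLASSES = ("sm-comp", "lg-comp", "non-comp")
_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

SMALL_SIZE_THRESHOLD = 3


@dataclass(frozen=True)
class Posteriors:
    """Class posteriors of one edge: small-, large- and non-co-complex."""

    sm: float
    lg: float
    non: float

    def __post_init__(self) -> None:
        total = self.sm + self.lg + self.non
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors sum to {total}, not 1")


# ---------------------------------------------------------------------------
# labelling


def load_complexes(lines: Iterable[str]) -> list[frozenset[str]]:
    """Parse a complex catalogue: one complex per line, tab-separated members.

    Complexes with fewer than two distinct members are rejected.
    """
    complexes = []
    for ln, line in enumerate(lines, 1):
        members = frozenset(tok for tok in line.strip().split("\t") if tok)
        if not members:
            continue
        if len(members) < 2:
            raise ValueError(f"complex on line {ln} has fewer than 2 distinct members")
        complexes.append(members)
    return complexes


def split_catalogue(
    complexes: Iterable[frozenset[str]],
    size_threshold: int = SMALL_SIZE_THRESHOLD,
) -> tuple[list[frozenset[str]], list[frozenset[str]]]:
    """Partition a catalogue into (small, large) by the size threshold."""
    small, large = [], []
    for cx in complexes:
        (small if len(cx) <= size_threshold else large).append(cx)
    return small, large


def label_edges(
    reliable: PairGraph,
    complexes: Iterable[frozenset[str]],
    size_threshold: int = SMALL_SIZE_THRESHOLD,
) -> dict[Pair, str]:
    """Label every reliable edge sm-comp / lg-comp / non-comp.

    lg-comp takes precedence: a pair co-occurring in both a large and a
    small complex is labelled lg-comp.
    """
    small, large = split_catalogue(complexes, size_threshold)

    def co_complex_pairs(cxs: list[frozenset[str]]) -> set[Pair]:
        pairs: set[Pair] = set()
        for cx in cxs:
            members = sorted(cx)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    pairs.add((a, b))
        return pairs

    lg_pairs = co_complex_pairs(large)
    sm_pairs = co_complex_pairs(small)

    labels: dict[Pair, str] = {}
    for pair, _ in reliable.edges():
        if pair in lg_pairs:
            labels[pair] = "lg-comp"
        elif pair in sm_pairs:
            labels[pair] = "sm-comp"
        else:
            labels[pair] = "non-comp"
    return labels


# ---------------------------------------------------------------------------
# MDL supervised discretization (Fayyad & Irani)


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _mdl_partition(values: np.ndarray, onehot: np.ndarray, cuts: list[float]) -> None:
    """Recursively add accepted cut points for one sorted value block."""
    n = len(values)
    if n < 2:
        return
    # candidate cuts: boundaries between runs of equal value where the two
    # adjacent runs are not both pure in the same single class
    change = np.flatnonzero(values[1:] != values[:-1]) + 1  # run starts
    if change.size == 0:
        return
    run_bounds = np.concatenate(([0], change, [n]))
    run_counts = np.add.reduceat(onehot, run_bounds[:-1], axis=0)

    cum = np.cumsum(run_counts, axis=0)
    total = cum[-1]
    ent_s = _entropy(total)
    k = int((total > 0).sum())

    best = None  # (weighted_entropy, split_index_in_runs)
    for r in range(len(run_counts) - 1):
        left_cls = run_counts[r] > 0
        right_cls = run_counts[r + 1] > 0
        if left_cls.sum() == 1 and right_cls.sum() == 1 and (left_cls == right_cls).all():
            continue  # not a class-boundary point
        left = cum[r]
        right = total - left
        n1, n2 = left.sum(), right.sum()
        went = (n1 / n) * _entropy(left) + (n2 / n) * _entropy(right)
        if best is None or went < best[0] - 1e-12:
            best = (went, r, left, right)

    if best is None:
        return
    went, r, left, right = best
    gain = ent_s - went
    k1 = int((left > 0).sum())
    k2 = int((right > 0).sum())
    delta = math.log2(3**k - 2) - (k * ent_s - k1 * _entropy(left) - k2 * _entropy(right))
    if gain <= (math.log2(n - 1) + delta) / n:
        return

    split = run_bounds[r + 1]
    cuts.append((values[split - 1] + values[split]) / 2.0)
    _mdl_partition(values[:split], onehot[:split], cuts)
    _mdl_partition(values[split:], onehot[split:], cuts)


def mdl_discretize(
    values: Sequence[float], labels: Sequence[str]
) -> list[float] | None:
    """MDL-accepted cut points for one feature, or None when removed.

    Cuts are midpoints between adjacent class-boundary values; binary splits
    are accepted recursively while the Fayyad–Irani minimum-description-
    length test holds.  A feature with no accepted top-level split (constant
    features in particular) carries no class information and is removed.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray([_CLASS_INDEX[lbl] for lbl in labels])
    if v.shape != y.shape:
        raise ValueError("values and labels length mismatch")
    order = np.argsort(v, kind="stable")
    v, y = v[order], y[order]
    onehot = np.zeros((len(v), len(CLASSES)))
    onehot[np.arange(len(v)), y] = 1.0

    cuts: list[float] = []
    _mdl_partition(v, onehot, cuts)
    if not cuts:
        return None
    return sorted(cuts)


class Discretizer:
    """Per-feature MDL discretization fitted on labelled edges.

    Attributes after :meth:`fit`: ``cuts_`` maps each retained feature to
    its ascending cut points; ``removed_`` lists the features MDL rejected.
    """

    def __init__(self) -> None:
        self.cuts_: dict[str, list[float]] = {}
        self.removed_: list[str] = []

    def fit(self, table: pd.DataFrame, labels: Sequence[str]) -> "Discretizer":
        self.cuts_ = {}
        self.removed_ = []
        for feature in table.columns:
            cuts = mdl_discretize(table[feature].to_numpy(), labels)
            if cuts is None:
                self.removed_.append(feature)
                logger.info("feature %s removed by MDL discretization", feature)
            else:
                self.cuts_[feature] = cuts
        return self

    @property
    def features(self) -> list[str]:
        return list(self.cuts_)

    def n_bins(self, feature: str) -> int:
        return len(self.cuts_[feature]) + 1

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Map raw feature values to bin codes for the retained features."""
        codes = {
            f: np.searchsorted(np.asarray(self.cuts_[f]), table[f].to_numpy(), side="right")
            for f in self.cuts_
        }
        return pd.DataFrame(codes, index=table.index)


# ---------------------------------------------------------------------------
# naive-Bayes maximum-likelihood model


@dataclass
class SSSModel:
    """Three-class naive-Bayes model over discretized edge features.

    ``cpt[feature]`` is a (3, n_bins) array of P(F = f | class), rows
    ordered sm-comp, lg-comp, non-comp.  With ``smoothing`` α > 0 the
    estimates are (n_{class,f} + α) / (n_class + α · n_bins); α = 0 gives
    the pure maximum-likelihood counts.
    """

    discretizer: Discretizer
    priors: np.ndarray
    cpt: dict[str, np.ndarray] = field(default_factory=dict)
    smoothing: float = 1.0

    def to_yaml(self) -> str:
        doc = {
            "classes": list(CLASSES),
            "smoothing": float(self.smoothing),
            "priors": [float(p) for p in self.priors],
            "features": {
                f: {
                    "cuts": [float(c) for c in self.discretizer.cuts_[f]],
                    "cpt": self.cpt[f].tolist(),
                }
                for f in self.discretizer.features
            },
            "removed": list(self.discretizer.removed_),
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SSSModel":
        doc = yaml.safe_load(text)
        if tuple(doc["classes"]) != CLASSES:
            raise ValueError("model file class order mismatch")
        disc = Discretizer()
        disc.removed_ = list(doc.get("removed", []))
        cpt = {}
        for f, entry in doc["features"].items():
            disc.cuts_[f] = [float(c) for c in entry["cuts"]]
            cpt[f] = np.asarray(entry["cpt"], dtype=float)
        return cls(
            discretizer=disc,
            priors=np.asarray(doc["priors"], dtype=float),
            cpt=cpt,
            smoothing=float(doc["smoothing"]),
        )


def learn_ml_params(
    codes: pd.DataFrame,
    labels: Sequence[str],
    discretizer: Discretizer,
    smoothing: float = 1.0,
) -> SSSModel:
    """Estimate class priors and per-feature conditional tables by counting."""
    y = np.asarray([_CLASS_INDEX[lbl] for lbl in labels])
    class_counts = np.bincount(y, minlength=3).astype(float)
    if (class_counts == 0).any():
        empty = [CLASSES[i] for i in np.flatnonzero(class_counts == 0)]
        raise ValueError(f"training set has no edges for classes: {empty}")

    cpt: dict[str, np.ndarray] = {}
    for f in discretizer.features:
        nb = discretizer.n_bins(f)
        counts = np.zeros((3, nb))
        np.add.at(counts, (y, codes[f].to_numpy()), 1.0)
        cpt[f] = (counts + smoothing) / (class_counts[:, None] + smoothing * nb)

    priors = class_counts / class_counts.sum()
    return SSSModel(discretizer=discretizer, priors=priors, cpt=cpt, smoothing=smoothing)


def naive_bayes_posteriors(model: SSSModel, codes: pd.DataFrame) -> pd.DataFrame:
    """Posterior P(class | features) per edge, computed in log space.

    Returns a DataFrame with columns P_sm, P_lg, P_non on the codes' index.
    Rows whose likelihood vanishes for all three classes (possible only with
    smoothing 0) raise, as the posterior is undefined.
    """
    n = len(codes)
    with np.errstate(divide="ignore"):
        logpost = np.tile(np.log(model.priors), (n, 1))
        for f in model.discretizer.features:
            logpost += np.log(model.cpt[f][:, codes[f].to_numpy()]).T

    finite = logpost.max(axis=1)
    if np.isneginf(finite).any():
        bad = codes.index[np.isneginf(finite)][0]
        raise ValueError(
            f"all class likelihoods are zero for edge {bad}; "
            "use smoothing > 0 to avoid zero-frequency annihilation"
        )
    logpost -= finite[:, None]
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    return pd.DataFrame(post, index=codes.index, columns=["P_sm", "P_lg", "P_non"])


def posteriors_to_dict(post: pd.DataFrame) -> dict[Pair, Posteriors]:
    return {
        pair: Posteriors(sm=row[0], lg=row[1], non=row[2])
        for pair, row in zip(post.index, post.to_numpy())
    }


# ---------------------------------------------------------------------------
# isolatedness


def iso_feature(
    posteriors: Mapping[Pair, Posteriors], reliable: PairGraph
) -> dict[Pair, float]:
    """ISO(a,b) = ISO2(a,b) + ISO3(a,b) on the reliable network.

    ISO2 is P_sm(a,b) times the product of P_non over every edge adjacent
    to the pair — high when the edge is probably isolated.  ISO3 sums, over
    each common neighbour c, the probability that {a, b, c} forms an
    all-small triangle with every edge leaving the triangle being
    non-co-complex.  Empty products are 1 (a fully isolated edge or
    triangle).
    """

    def p(x: str, y: str) -> Posteriors:
        return posteriors[(x, y) if x < y else (y, x)]

    def log_non_leaving(members: tuple[str, ...]) -> float:
        """Sum of log P_non over reliable edges from `members` to outside."""
        total = 0.0
        inside = set(members)
        for x in members:
            for y in sorted(reliable.neighbors(x) - inside):
                non = p(x, y).non
                if non == 0.0:
                    return -math.inf
                total += math.log(non)
        return total

    iso: dict[Pair, float] = {}
    for (a, b), _ in reliable.edges():
        p_ab = p(a, b)
        iso2 = p_ab.sm * math.exp(log_non_leaving((a, b))) if p_ab.sm > 0 else 0.0

        iso3 = 0.0
        for c in sorted(reliable.common_neighbors(a, b)):
            tri = p_ab.sm * p(a, c).sm * p(b, c).sm
            if tri > 0:
                iso3 += tri * math.exp(log_non_leaving((a, b, c)))
        iso[(a, b)] = iso2 + iso3
    return iso


# ---------------------------------------------------------------------------
# full pipeline step


def sss_weight(
    reliable: PairGraph,
    features: pd.DataFrame,
    labels: Mapping[Pair, str],
    smoothing: float = 1.0,
    include_iso: bool = True,
) -> tuple[dict[Pair, Posteriors], SSSModel]:
    """Run the six SSS steps and return final posteriors plus the model.

    ``features`` is the twelve-column table over the reliable edges
    (see :func:`sssx.features.assemble_feature_table`); ``labels`` maps each
    edge to its training class.  With ``include_iso=False`` (the no-ISO
    ablation) steps 4–6 are skipped and the step-3 posteriors are returned.
    """
    missing = [pair for pair in (p for p, _ in reliable.edges()) if pair not in labels]
    if missing:
        raise ValueError(f"{len(missing)} reliable edges lack labels, e.g. {missing[0]}")
    y = [labels[pair] for pair in features.index]

    disc = Discretizer().fit(features, y)
    if not disc.features:
        raise ValueError("every feature was removed by MDL discretization")
    codes = disc.transform(features)
    model = learn_ml_params(codes, y, disc, smoothing)
    post = naive_bayes_posteriors(model, codes)

    if not include_iso:
        return posteriors_to_dict(post), model

    iso = iso_feature(posteriors_to_dict(post), reliable)
    iso_values = np.array([iso[pair] for pair in features.index])
    iso_cuts = mdl_discretize(iso_values, y)
    if iso_cuts is None:
        logger.warning("ISO feature removed by MDL; final posteriors exclude ISO")
        return posteriors_to_dict(post), model

    table_iso = features.copy()
    table_iso["ISO"] = iso_values
    disc2 = Discretizer()
    disc2.cuts_ = dict(disc.cuts_)
    disc2.cuts_["ISO"] = iso_cuts
    disc2.removed_ = list(disc.removed_)
    codes2 = disc2.transform(table_iso)
    model2 = learn_ml_params(codes2, y, disc2, smoothing)
    post2 = naive_bayes_posteriors(model2, codes2)
    return posteriors_to_dict(post2), model2
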