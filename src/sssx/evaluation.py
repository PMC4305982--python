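"""Cross-validation and exact-match precision-recall evaluation.

Random sub-sampling cross-validation: in each round t% of the reference
complexes (large and small alike) are drawn as test complexes and the rest
train the weighting model.  Predictions are matched against the *small* test
complexes only, and matching is exact set equality — a predicted cluster
counts only if it is identical to a reference complex.

At a score threshold d,

    Recall_d    = fraction of small test complexes matched by some
                  prediction scoring >= d;
    Precision_d = matched predictions scoring >= d, divided by the
                  predictions scoring >= d that do not match a *training*
                  complex (predicting a training complex back is not an
                  error for a supervised method, merely uninformative).

The PR curve takes every distinct prediction score as a threshold;
thresholds whose precision denominator is zero are omitted.  The AUC
integrates precision over recall by trapezoid, anchored at recall 0 with
the precision of the strictest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Sequence

import numpy as np

from .extract import PredictedCluster
from .sss import SMALL_SIZE_THRESHOLD

__all__ = [
    "CVSplit",
    "PRCurve",
    "split_complexes",
    "match_exact",
    "pr_curve",
    "score_to_precision_map",
]


@dataclass(frozen=True)
class CVSplit:
    """One cross-validation round: disjoint test/train complex lists."""

    round_index: int
    test: tuple[frozenset[str], ...]
    train: tuple[frozenset[str], ...]


@dataclass(frozen=True)
class PRCurve:
    """Exact-match precision-recall curve: (threshold, recall, precision) points."""

    points: tuple[tuple[float, float, float], ...]
    auc: float

    @property
    def thresholds(self) -> list[float]:
        return [d for d, _, _ in self.points]


def split_complexes(
    catalogue: Sequence[frozenset[str]],
    t_percent: float = 90.0,
    rounds: int = 10,
    seed: int = 0,
) -> list[CVSplit]:
    """Independent random sub-sampling splits: t% test, remainder train."""
    if not 0 < t_percent < 100:
        raise ValueError(f"t_percent must be in (0, 100), got {t_percent}")
    n = len(catalogue)
    n_test = int(n * t_percent / 100)
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"t={t_percent}% of {n} complexes leaves an empty test or training set"
        )
    rng = np.random.default_rng(seed)
    splits = []
    for r in range(rounds):
        idx = rng.permutation(n)
        test = tuple(catalogue[i] for i in sorted(idx[:n_test]))
        train = tuple(catalogue[i] for i in sorted(idx[n_test:]))
        splits.append(CVSplit(round_index=r, test=test, train=train))
    return splits


def match_exact(cluster: Iterable[str], complex_members: Iterable[str]) -> bool:
    """Exact match: set equality between prediction and reference complex."""
    return frozenset(cluster) == frozenset(complex_members)


def pr_curve(
    predictions: Sequence[PredictedCluster],
    test_small: Iterable[frozenset[str]],
    train: Iterable[frozenset[str]] = (),
) -> PRCurve:
    """Precision-recall curve of ranked predictions against small test complexes."""
    test_set = {frozenset(c) for c in test_small}
    train_set = {frozenset(c) for c in train}
    if not test_set:
        raise ValueError("empty test complex set")
    # exact matching + disjoint reference sets: a prediction cannot match both
    assert not (test_set & train_set), "test and training complexes overlap"

    ranked = sorted(predictions, key=lambda cl: -cl.score)
    scores = np.array([cl.score for cl in ranked])
    is_test = np.array([cl.member_set in test_set for cl in ranked])
    not_train = np.array([cl.member_set not in train_set for cl in ranked])

    # recall counts each test complex at most once: flag first match per complex
    seen: set[frozenset[str]] = set()
    first_match = np.zeros(len(ranked), dtype=bool)
    for i, cl in enumerate(ranked):
        if is_test[i] and cl.member_set not in seen:
            seen.add(cl.member_set)
            first_match[i] = True

    cum_matched_complexes = np.cumsum(first_match)
    cum_matched_preds = np.cumsum(is_test)
    cum_eligible = np.cumsum(not_train)

    points = []
    for d in sorted(set(scores), reverse=True):
        i = int(np.searchsorted(-scores, -d, side="right")) - 1  # last idx with score >= d
        if cum_eligible[i] == 0:
            continue
        recall = cum_matched_complexes[i] / len(test_set)
        precision = cum_matched_preds[i] / cum_eligible[i]
        points.append((float(d), float(recall), float(precision)))

    return PRCurve(points=tuple(points), auc=_pr_auc(points))


def _pr_auc(points: Sequence[tuple[float, float, float]]) -> float:
    """Trapezoidal area under (recall, precision), anchored at recall 0.

    The anchor carries the strictest threshold's precision to recall 0, so a
    prediction list that is exactly the test catalogue integrates to 1.
    Multiple points at equal recall contribute no width.
    """
    if not points:
        return 0.0
    rp = sorted((r, p) for _, r, p in points)
    recalls = [0.0] + [r for r, _ in rp]
    precisions = [rp[0][1]] + [p for _, p in rp]
    return float(np.trapezoid(precisions, recalls))


def score_to_precision_map(cv_curves: Sequence[PRCurve]):
    """Map a cluster score to its cross-validation-estimated precision.

    For each round's curve the precision at the largest threshold <= the
    query score is taken (step interpolation; queries above the largest
    threshold use it, queries below the smallest get that round's last
    precision at its smallest threshold — i.e. the most permissive point);
    the estimate is the mean over rounds that have any threshold.
    """
    if not cv_curves:
        raise ValueError("need at least one PR curve")

    prepared = []
    for curve in cv_curves:
        pts = sorted(curve.points)  # ascending threshold
        if pts:
            prepared.append((np.array([d for d, _, _ in pts]),
                             np.array([p for _, _, p in pts])))

    def estimate(score: float) -> float:
        vals = []
        for thresholds, precisions in prepared:
            i = int(np.searchsorted(thresholds, score, side="right")) - 1
            vals.append(precisions[max(i, 0)])
        return float(np.mean(vals)) if vals else 0.0

    return estimate


def small_complexes(
    catalogue: Iterable[frozenset[str]], size_threshold: int = SMALL_SIZE_THRESHOLD
) -> list[frozenset[str]]:
    """The small (size 2–3) complexes of a catalogue."""
    return [c for c in catalogue if len(c) <= size_threshold]
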