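"""End-to-end orchestration: weighting, extraction and cross-validation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np

from .config import PipelineConfig
from .evaluation import PRCurve, pr_curve, small_complexes, split_complexes
from .extract import PredictedCluster, score_clusters
from .features import assemble_feature_table
from .graph import PairGraph
from .sss import Posteriors, SSSModel, label_edges, sss_weight

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "cross_validate", "density_rank_clusters"]

Pair = tuple[str, str]


@dataclass
class PipelineResult:
    posteriors: dict[Pair, Posteriors]
    model: SSSModel
    clusters: list[PredictedCluster]


def run_pipeline(
    reliable: PairGraph,
    graphs: Mapping[str, PairGraph],
    train_complexes: Sequence[frozenset[str]],
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Weight the reliable network with SSS and extract ranked small clusters."""
    if len(reliable) == 0:
        raise ValueError("empty reliable network")
    config.log()

    network_proteins = reliable.proteins()
    n_outside = sum(1 for cx in train_complexes if not cx <= network_proteins)
    if n_outside:
        # such complexes still label whichever of their co-complex edges the
        # network observed, so they are kept
        logger.warning(
            "%d training complexes contain proteins absent from the network",
            n_outside,
        )

    features = assemble_feature_table(
        reliable, graphs, lam=config.lam, shared_iterations=config.shared_iterations
    )
    labels = label_edges(reliable, train_complexes)
    posteriors, model = sss_weight(
        reliable,
        features,
        labels,
        smoothing=config.smoothing,
        include_iso=config.include_iso,
    )
    clusters = score_clusters(posteriors, reliable, min_score=config.min_score)
    logger.info(
        "pipeline: %d reliable edges, %d retained features, %d candidate clusters",
        len(reliable), len(model.discretizer.features), len(clusters),
    )
    return PipelineResult(posteriors=posteriors, model=model, clusters=clusters)


def density_rank_clusters(reliable: PairGraph) -> list[PredictedCluster]:
    """Baseline ranking: candidates scored by raw weighted density.

    Every edge scores its reliability, every triangle the mean of its three
    edge reliabilities — the scoring a plain reliability-weighted network
    supports, with no size-specific weighting or cohesiveness.
    """
    clusters = [
        PredictedCluster((a, b), 1.0, w) for (a, b), w in reliable.edges()
    ]
    for a, b, c in reliable.triangles():
        w = (reliable.score(a, b) + reliable.score(a, c) + reliable.score(b, c)) / 3.0
        clusters.append(PredictedCluster((a, b, c), 1.0, w))
    clusters.sort(key=lambda cl: (-cl.score, cl.members))
    return clusters


def cross_validate(
    reliable: PairGraph,
    graphs: Mapping[str, PairGraph],
    catalogue: Sequence[frozenset[str]],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[PRCurve], float]:
    """Random sub-sampling CV of the full SSS + Extract pipeline.

    Per round, t% of the catalogue (large and small) is held out for
    testing; the rest trains the weighting.  Predictions are matched against
    the small test complexes only.  Returns the per-round PR curves and the
    mean AUC.
    """
    splits = split_complexes(
        catalogue, t_percent=config.t_percent, rounds=config.rounds, seed=config.seed
    )
    curves = []
    for split in splits:
        result = run_pipeline(reliable, graphs, list(split.train), config)
        test_small = small_complexes(split.test)
        curve = pr_curve(result.clusters, test_small, split.train)
        logger.info("round %d: AUC %.4f", split.round_index, curve.auc)
        curves.append(curve)
    mean_auc = float(np.mean([c.auc for c in curves]))
    return curves, mean_auc
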