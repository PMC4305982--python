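"""Pipeline configuration with the method's published defaults."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace

import yaml

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings for a full run.

    k
        number of top-reliability PPI edges kept for weighting (10000).
    lam
        NBC dampening factor λ capping the effective neighbourhood size.
    smoothing
        pseudocount on the naive-Bayes conditional tables; 0 gives the pure
        maximum-likelihood estimates.
    string_threshold
        STRING pairs are kept only with score strictly greater than this.
    t_percent / rounds
        cross-validation: per round, t% of complexes test, the rest train.
    include_iso
        False skips the isolatedness steps (the no-ISO ablation).
    """

    k: int = 10000
    lam: float = 10.0
    smoothing: float = 1.0
    string_threshold: float = 0.5
    shared_iterations: int = 2
    t_percent: float = 90.0
    rounds: int = 10
    min_score: float = 0.0
    include_iso: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        doc = yaml.safe_load(text) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def log(self) -> None:
        logger.info("resolved configuration:\n%s", self.to_yaml())
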