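"""Synthetic PPI benchmark networks with planted small and large complexes.

The generator emulates the structure the weighting stage exploits in real
interactomes: a catalogue of planted complexes whose sizes follow the
empirical pattern (most complexes are small, large sizes power-law
distributed), three evidence sources whose scores are drawn from
class-conditional Beta distributions (small-, large- and non-co-complex
pairs), missing within-complex edges (false negatives), and spurious
background edges over non-co-complex pairs (Erdős–Rényi).  A small fraction
of complexes reuses one protein from an earlier complex, mimicking
core-attachment overlap between distinct complexes.

Everything is determined by the seed, so any experiment on generated data
is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graph import PairGraph, canonical_pair
from .reliability import top_k_filter

__all__ = ["SynthConfig", "SyntheticDataset", "generate"]

Pair = tuple[str, str]

# class-conditional Beta(a, b) score parameters per source; sm/lg score
# distributions are deliberately close so that size-specific separation must
# come from topology and supervision, as in real interactomes where a
# detection method cannot see complex size
DEFAULT_SCORE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "PPI": {"sm-comp": (5.0, 2.0), "lg-comp": (5.0, 2.0), "non-comp": (2.0, 4.0)},
    "STRING": {"sm-comp": (4.0, 2.0), "lg-comp": (4.0, 2.0), "non-comp": (1.5, 4.0)},
    "LIT": {"sm-comp": (3.0, 2.0), "lg-comp": (2.0, 2.0), "non-comp": (1.0, 5.0)},
}

# per-source probability that a pair present in the PPI network is also
# observed by the other sources (PPI itself defines the network)
DEFAULT_OBSERVATION_PROB = {"PPI": 1.0, "STRING": 0.7, "LIT": 0.5}


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; the defaults are the package's study conditions."""

    n_proteins: int = 300
    n_small2: int = 15
    n_small3: int = 15
    n_large: int = 10
    large_exponent: float = 2.0
    large_max_size: int = 12
    overlap_prob: float = 0.1
    fn_rate: float = 0.1
    spurious_rate: float = 0.004
    spurious_attach_bias: float = 0.5
    spurious_triangle_frac: float = 0.3
    # functional modules: groups of co-functional (not co-complexed) proteins
    # that are densely connected in STRING and co-cited in LIT, emulating
    # pathway/co-citation structure that is association, not complex
    n_modules: int = 15
    module_size_range: tuple[int, int] = (5, 15)
    module_complex_bias: float = 0.5
    module_edge_prob: float = 0.5
    score_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            s: dict(d) for s, d in DEFAULT_SCORE_PARAMS.items()
        }
    )
    observation_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OBSERVATION_PROB)
    )
    # overrides for spurious edges; None falls back to the non-comp entries
    # of score_params / observation_prob
    spurious_score_params: dict[str, tuple[float, float]] | None = None
    spurious_observation_prob: dict[str, float] | None = None
    k: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (("fn_rate", self.fn_rate), ("spurious_rate", self.spurious_rate),
                           ("overlap_prob", self.overlap_prob)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.large_max_size < 4:
            raise ValueError("large complexes have size > 3")

    def high_noise(self) -> "SynthConfig":
        """A noisy variant emulating high-reliability false-positive PPIs.

        More within-complex edges go missing, and spurious edges become
        both more frequent and deceptive: they preferentially attach to
        complex proteins and carry PPI scores drawn from the co-complex
        distribution (experimental false positives reproduce with high
        apparent reliability), while being rarely corroborated by STRING or
        LIT.  Raw per-source topology around small complexes is then
        misleading, and the isolatedness of the posterior-weighted network
        carries the discriminating signal.
        """
        return replace(
            self,
            fn_rate=0.25,
            spurious_rate=min(1.0, 2.5 * self.spurious_rate),
            spurious_attach_bias=0.8,
            spurious_triangle_frac=0.6,
            spurious_score_params={"PPI": (5.0, 2.0)},
            spurious_observation_prob={"STRING": 0.25, "LIT": 0.15},
        )

    @classmethod
    def large_interactome(cls, seed: int = 0) -> "SynthConfig":
        """A catalogue- and network-scale benchmark.

        About 400 planted complexes (two thirds small) on 2000 proteins,
        so a 90/10 test/train split still leaves a usable training set —
        the regime the cross-validation protocol is designed for.
        """
        return cls(
            n_proteins=2000,
            n_small2=130,
            n_small3=130,
            n_large=140,
            spurious_rate=0.0008,
            n_modules=60,
            seed=seed,
        )


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated evidence graphs, reliable network and ground-truth catalogue."""

    graphs: dict[str, PairGraph]
    reliable: PairGraph
    catalogue: tuple[frozenset[str], ...]
    config: SynthConfig


def _plant_complexes(config: SynthConfig, rng: np.random.Generator) -> list[frozenset[str]]:
    proteins = [f"P{i:04d}" for i in range(config.n_proteins)]

    sizes = [2] * config.n_small2 + [3] * config.n_small3
    if config.n_large:
        support = np.arange(4, config.large_max_size + 1)
        weights = support.astype(float) ** -config.large_exponent
        weights /= weights.sum()
        sizes += [int(s) for s in rng.choice(support, size=config.n_large, p=weights)]

    pool = list(proteins)
    rng.shuffle(pool)
    if sum(sizes) > len(pool):
        raise ValueError(
            f"cannot plant complexes totalling {sum(sizes)} members "
            f"among {config.n_proteins} proteins"
        )

    catalogue: list[frozenset[str]] = []
    used: list[str] = []
    for size in sizes:
        members: set[str] = set()
        if catalogue and used and rng.random() < config.overlap_prob:
            members.add(used[int(rng.integers(len(used)))])  # core-attachment reuse
        while len(members) < size:
            members.add(pool.pop())
        catalogue.append(frozenset(members))
        used.extend(sorted(members))  # deterministic order regardless of hash seed
    return catalogue


def generate(config: SynthConfig) -> SyntheticDataset:
    """Generate the three evidence graphs, reliable network and catalogue."""
    rng = np.random.default_rng(config.seed)
    catalogue = _plant_complexes(config, rng)
    proteins = [f"P{i:04d}" for i in range(config.n_proteins)]

    # true class per co-complex pair, large complexes taking precedence
    pair_class: dict[Pair, str] = {}
    for cx in catalogue:
        label = "sm-comp" if len(cx) <= 3 else "lg-comp"
        members = sorted(cx)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pair = (a, b)
                if label == "lg-comp" or pair not in pair_class:
                    pair_class[pair] = label

    # PPI edge universe: co-complex pairs minus false negatives ...
    edges: dict[Pair, str] = {}
    for pair in sorted(pair_class):
        if rng.random() >= config.fn_rate:
            edges[pair] = pair_class[pair]
    # ... plus spurious edges over non-co-complex pairs, preferentially
    # attached to complex proteins (false positives cluster around the
    # well-studied parts of the interactome)
    n = len(proteins)
    n_pairs = n * (n - 1) // 2
    complex_proteins = sorted({p for cx in catalogue for p in cx})
    n_spurious = rng.binomial(n_pairs - len(pair_class), config.spurious_rate)
    added = 0
    true_edges = sorted(edges)
    while added < n_spurious:
        if true_edges and rng.random() < config.spurious_triangle_frac:
            # wedge-closing false positives: two extraneous interactions
            # suffice to embed a co-complex edge inside a spurious triangle
            a, b = true_edges[int(rng.integers(len(true_edges)))]
            c = proteins[int(rng.integers(n))]
            if c in (a, b):
                continue
            for x in (a, b):
                pair = canonical_pair(x, c)
                if pair not in pair_class and pair not in edges:
                    edges[pair] = "spurious"
                    added += 1
            continue
        if complex_proteins and rng.random() < config.spurious_attach_bias:
            a = complex_proteins[int(rng.integers(len(complex_proteins)))]
        else:
            a = proteins[int(rng.integers(n))]
        b = proteins[int(rng.integers(n))]
        if a == b:
            continue
        pair = canonical_pair(a, b)
        if pair in pair_class or pair in edges:
            continue
        edges[pair] = "spurious"
        added += 1

    sp_scores = config.spurious_score_params or {}
    sp_obs = config.spurious_observation_prob or {}
    graphs: dict[str, PairGraph] = {}
    for source in ("PPI", "STRING", "LIT"):
        g = PairGraph(source=source)
        for pair in sorted(edges):
            cls = edges[pair]
            if cls == "spurious":
                obs = sp_obs.get(source, config.observation_prob[source])
                a_param, b_param = sp_scores.get(
                    source, config.score_params[source]["non-comp"]
                )
            else:
                obs = config.observation_prob[source]
                a_param, b_param = config.score_params[source][cls]
            if obs < 1.0 and rng.random() >= obs:
                continue
            g.add_edge(*pair, float(rng.beta(a_param, b_param)))
        graphs[source] = g

    # functional-module edges appear in STRING/LIT only: dense association
    # structure with co-complex-like scores but no physical interaction
    lo, hi = config.module_size_range
    for _ in range(config.n_modules):
        size = int(rng.integers(lo, hi + 1))
        members: set[str] = set()
        while len(members) < size:
            if complex_proteins and rng.random() < config.module_complex_bias:
                members.add(complex_proteins[int(rng.integers(len(complex_proteins)))])
            else:
                members.add(proteins[int(rng.integers(n))])
        ordered = sorted(members)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                if (a, b) in pair_class:
                    continue
                for source in ("STRING", "LIT"):
                    if rng.random() < config.module_edge_prob:
                        a_param, b_param = config.score_params[source]["sm-comp"]
                        if (a, b) not in graphs[source]:
                            graphs[source].add_edge(a, b, float(rng.beta(a_param, b_param)))

    reliable = top_k_filter(graphs["PPI"].edge_dict(), config.k)
    return SyntheticDataset(
        graphs=graphs,
        reliable=reliable,
        catalogue=tuple(catalogue),
        config=config,
    )
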