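# Methods

This note documents the model implemented by `sssx`, the numerical and
design choices that were genuinely open, the synthetic benchmark and what
it does and does not emulate, and known limitations.

## Problem and model

A PPI network observes physical interactions with substantial noise in both
directions. Small complexes (2–3 distinct proteins) are dense subgraphs of
trivial shape — edges and triangles — so topology alone cannot separate
them from the network's abundant incidental edges and triangles, and the
co-complex signal of an edge differs sharply by complex size: edges of
large complexes sit in dense, high-degree neighbourhoods, edges of small
complexes in sparse, isolated ones. `sssx` therefore learns *separate*
posterior probabilities per edge for small-co-complex, large-co-complex and
non-co-complex membership, and extracts candidates with size-specific
scores.

### Reliability stage

Raw evidence records (pair, detection method, publication) are combined by
a Noisy-Or model: each method *i* has reliability *relᵢ*, the fraction of
its detected pairs whose proteins share a high-level cellular-component GO
annotation, and

    reliability(a, b) = 1 − ∏_{i ∈ E_{a,b}} (1 − relᵢ)^{n_{i,a,b}}

where *n* counts the method's detections of that pair. Duplicate counting
across source databases is prevented by publication-ID deduplication, with
source priority configurable (first-declared wins by default). Pre-scored
consolidated datasets enter the same scheme as ten pseudo-methods, one per
score decile (left-closed bins, 1.0 in the top bin — this avoids a
degenerate eleventh bin). The network to be weighted keeps the top
k = 10 000 edges by reliability; ties at the cutoff break by canonical pair
order so the selection is reproducible. The colocalization predicate is an
input: the package deliberately does not traverse the GO ontology.

### Features

Per data source (PPI reliability, STRING > 0.5 strictly, LIT Jaccard of
publication sets), three topological features are computed on the source's
*full* graph — the top-k filter applies only to the network being weighted,
while features describe the evidence source:

* **DEG(a,b)** — summed scores of edges leaving the pair; excludes the
  (a, b) edge itself.
* **SHARED(a,b)** — iterative AdjustCD with two iterations: edge weights
  are re-estimated from the weighted common-neighbour overlap,
  `w_k(u,v) = Σ_{x∈N_u∩N_v} (w_{k−1}(u,x) + w_{k−1}(v,x)) / (λ_u + deg(u) + λ_v + deg(v))`,
  where `λ_u = max(0, avg_deg − deg(u))` penalizes low-degree proteins
  toward the current iteration's mean weighted degree. Graph topology is
  fixed across iterations; only weights update.
* **NBC(a,b)** — weighted density among the pair's neighbourhood
  N_{a,b} = (N_a ∪ N_b) \ {a, b}: the sum of scores over ordered neighbour
  pairs divided by m(m−1), m = min(|N_{a,b}|, λ). The ordered-pair
  convention makes NBC a density on the scale of the edge weights. The
  dampening factor λ defaults to 10 and caps the denominator so large
  neighbourhoods with a dense core are not diluted; one global λ serves all
  sources.

A missing pair in a source scores 0. LIT pairs are kept whenever nonzero;
no threshold is applied.

### SSS weighting

Edges are labelled from a training catalogue: `lg-comp` if the pair
co-occurs in a large training complex (precedence), else `sm-comp` if in a
small one, else `non-comp`. Six steps:

1. Fayyad–Irani MDL supervised discretization per feature. Candidate cuts
   are midpoints between adjacent runs of equal value that are not both
   pure in the same class (the boundary-point theorem); binary splits
   recurse while the MDL gain test
   `Gain > (log₂(N−1) + log₂(3^k − 2) − [k·Ent(S) − k₁·Ent(S₁) − k₂·Ent(S₂)]) / N`
   holds. A feature with no accepted top-level split is removed — built-in
   feature selection. Removed features are excluded from the model and the
   model file; the per-stage log records them.
2. Class priors and per-feature conditional tables by counting. A
   pseudocount α (default 1) smooths `P(F=f | class) = (n+α)/(n_class+α·bins)`;
   α = 0 gives the literal maximum-likelihood estimates but lets a single
   unseen value annihilate a class posterior, so add-one is the default.
3. Naive-Bayes posteriors per edge, accumulated in log space and
   renormalized exactly.
4. Isolatedness from the initial posteriors, on the reliable network
   (the only edges carrying posteriors):
   `ISO2(a,b) = P_sm(a,b) · ∏ P_non(x,y)` over edges (x, y) leaving
   {a, b}, and `ISO3(a,b) = Σ_{c∈N_a∩N_b} P_sm(a,b)·P_sm(a,c)·P_sm(b,c) ·
   ∏ P_non` over edges leaving {a, b, c}. Empty products are 1: a fully
   isolated edge scores its own P_sm.
5. ISO is MDL-discretized and its conditional tables learned. If MDL
   rejects ISO the final posteriors simply exclude it (logged).
6. Posteriors are recomputed with all retained features plus ISO. Steps
   4–6 run exactly once; the no-ISO ablation skips them, returning the
   step-3 posteriors unchanged.

Discretization and tables are fitted on the labelled edges (in
cross-validation, all edges labelled from training complexes) and applied
to every edge.

### Extract

With common-neighbour triangle mass
`T(a,b,x) = P_sm(a,b)·P_sm(a,x)·P_sm(b,x)`:

    P′sm2(a,b)     = P_sm(a,b) − Σ_{x∈N_a∩N_b} T(a,b,x)
    P′sm3,abc(a,b) = P_sm(a,b) − Σ_{x∈N_a∩N_b \ {c}} T(a,b,x)

Negative values are clamped to 0 — with several strong incident triangles
the subtraction exceeds P_sm; these are scores, not probabilities.
Cohesiveness divides the internal component score by internal plus outgoing
co-complex weight (P_sm + P_lg of every edge leaving the cluster), with
0/0 defined as 0 (such clusters carry no evidence). Final scores:

    score(a,b)   = Coh(a,b) · P′sm2(a,b)
    score(a,b,c) = Coh(a,b,c) · (P′sm3,abc(a,b) + P′sm3,abc(a,c) + P′sm3,abc(b,c)) / 3

Candidates are all edges and all triangles of the reliable network; a
triangle and its member edges may both appear, ranked independently —
suppression of constituents is left to the consumer. Ranking is
deterministic: descending score, ties by canonical member order. Clusters
scoring 0 are omitted by default.

## Evaluation protocol

Random sub-sampling cross-validation: per round, t % of the catalogue
(large and small complexes alike, sampled uniformly) is held out as test;
the remainder trains the weighting. Predictions are matched by exact set
equality against the *small* test complexes only. At threshold d, recall is
the fraction of small test complexes matched by a prediction scoring ≥ d
(each counted once); precision is matched predictions over predictions
matching no *training* complex — re-predicting a training complex is
uninformative for a supervised method, not an error. Thresholds with an
empty precision denominator are omitted.

PR-AUC integrates precision over recall by trapezoid with the curve
anchored at (recall 0, precision of the strictest threshold). The anchor is
a deliberate convention: without it a prediction list that reproduces the
test catalogue exactly would integrate to 1 − 1/n rather than 1, making
the statistic depend on test-set size; no extrapolation is performed beyond
the highest achieved recall. Per-round curves are retained; the headline
statistic is the mean AUC across rounds. The score→precision map (for
filtering novel predictions by estimated precision) steps to the largest
threshold ≤ the query score and averages across rounds.

## Synthetic benchmark

The generator plants a catalogue — n₂ size-2 and n₃ size-3 complexes plus
large complexes with power-law sizes (exponent 2, support 4–12) — with
occasional single-protein reuse between complexes (core-attachment-style
overlap). Within-complex edges are dropped at the false-negative rate;
per-source scores are Beta-distributed conditional on the pair's class,
with small- and large-co-complex distributions deliberately identical by
default so that size separation must come from supervision and topology,
as no detection method observes complex size.

Noise is modelled on how real false positives behave, not as uniform
background:

* spurious PPIs preferentially attach to complex proteins
  (well-studied regions accumulate false positives);
* a fraction close wedges, embedding true edges in spurious triangles —
  two extraneous interactions suffice to disguise a heterodimer as a
  triangle;
* STRING and LIT carry dense *functional-module* structure (pathway
  membership, co-citation) with co-complex-like scores but no physical
  interaction. This matters: without it, topology features computed on
  STRING/LIT act as already-denoised networks and the isolatedness feature
  is redundant; with it, ISO's use of the *integrated* posterior network
  provides information no single-source feature carries.
* In the high-noise variant, spurious PPIs additionally carry co-complex-
  like reliability scores while lacking STRING/LIT corroboration.

Default conditions: 300 proteins, 15 + 15 small and 10 large complexes,
10 % false negatives, spurious rate 0.004, 15 functional modules.
`SynthConfig.large_interactome()` scales to 2000 proteins and ~400
complexes (two thirds small) so that a 90/10 test/train split — the
real-use regime of predicting many unknown complexes from few known ones —
still leaves a usable training set; on the 40-complex default catalogue the
synthetic cross-validation experiments use t = 50 % instead, since 90 %
would leave ~4 training complexes and empty classes. Benchmark problem
sizes (rounds, seeds) in the tests and acceptance script are chosen to keep
the full run in the low tens of seconds while averaging out split noise.

What the generator does **not** emulate: realistic interactome degree
distributions, method- or bait-specific detection biases, score
correlations between sources beyond class conditioning, and catalogue
incompleteness (reference complexes missing from the catalogue appearing
as "false positives"). Passing benchmarks therefore demonstrate the
machinery's correctness and the claimed qualitative orderings — supervised
size-specific weighting ≫ raw-density ranking; isolatedness helps under
deceptive noise; performance degrades with noise — not absolute
performance on any real interactome.

## Numerical choices and degenerate inputs

* Probability products (Noisy-Or, naive Bayes, ISO) accumulate in log
  space; `log1p`/`expm1` guard the Noisy-Or complement; a zero factor
  short-circuits.
* Posterior normalization subtracts the max log before exponentiation; an
  all-zero likelihood row (possible only with α = 0) raises rather than
  returning arbitrary values.
* MDL entropy uses base-2 logs; equal-gain cuts resolve to the leftmost.
* Self-pairs are rejected at construction; all pair keys are canonical
  (lexicographically sorted), making every output file deterministic and
  diff-stable.
* Empty test sets, empty training classes, infeasible generator counts and
  out-of-range rates raise with specific messages instead of propagating
  NaNs.

## Limitations

* Naive-Bayes independence is clearly violated (the nine topology features
  correlate strongly); posteriors are therefore sharper than calibrated
  probabilities. Ranking, not calibration, is what Extract consumes.
* ISO is computed once from step-3 posteriors; it is not iterated to a
  fixed point, matching the six-step procedure.
* Candidates are limited to single edges and closed triangles of the
  reliable network: a size-3 complex that lost an internal edge to a false
  negative is unreachable, which bounds recall under noise.
* Exact-match evaluation gives no credit for near misses; AUCs are
  conservative and small in absolute terms.
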