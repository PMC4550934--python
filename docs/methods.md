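# Methods

## Scope and model

The package treats a curated disease interactome as a simple undirected
graph: nodes are protein accessions, edges are interactions retained at a
combined-score threshold (default 0.4, the conventional STRING
medium-confidence cutoff). Scores in [0, 1] are kept as edge weights for
bookkeeping but all topological statistics are computed on the binary
graph — the analyses characterize wiring, not evidence strength. Duplicate
pairs (STRING files list both directions) collapse to one edge keeping the
maximum score; self-loops are dropped and counted.

## Rich-club analysis

Raw coefficient: φ(k) = 2·E_>k / (N_>k(N_>k − 1)) for every threshold k
from 0 to max degree − 1, computed incrementally in O(|E|) by sweeping k
downward and adding each entering node's edges to members already present.
φ is *undefined* (NaN) where N_>k < 2 — reporting 0 there would fake the
absence of a club — and undefined thresholds are excluded from all range
logic.

Normalization: ρ(k) = φ(k)/⟨φ_rand(k)⟩ over an ensemble of degree-preserving
randomizations. Each member applies 10 accepted double edge swaps per edge
(a standard mixing heuristic, configurable); candidate swaps that would
create a self-loop or duplicate edge are rejected, so the degree sequence is
preserved *exactly* and members stay simple. The ensemble mean is the
default normalizer (the median is available); an empirical per-k p-value
(fraction of members with φ_rand ≥ φ) is reported alongside, though the
club call itself uses only ρ. Connectivity-preserving rewiring is available
behind a flag but off by default — rich-club counting does not require
connected nulls. Default ensemble size is 1,000, configurable upward; the
desk-scale analyses and validation runs use 50–200 members, which is ample
for a stable mean φ_rand at thresholds where N_>k is not tiny.

Delimitation. The significant range is the longest contiguous run of
defined ρ(k) > 1; the peak is the argmax within it (ties go to the smallest
k and are logged). The **core** is read from the contiguous run of
ρ(k) > 1.3: by default all nodes with degree ≥ the run's lower bound
(`core_rule="min"`). The alternative reading — nodes whose degree falls
*inside* the run (`core_rule="range"`) — is exposed but not default, for a
structural reason: the maximum-degree node's degree always exceeds every
defined threshold k, so an in-range rule can never include the club's top
hubs, which is incoherent for a structure defined by densely
interconnected hubs (and it measurably depresses recovery of planted cores
from ~1.0 to ~0.7). The **strongest component** is the set of nodes with
degree > k*, where k* is the smallest threshold from which φ ≥ 0.95 holds
for every larger defined threshold — a hard-cutoff reading of "φ plateaus
near 1".

Frequency contrast uses Welch's two-tailed t-test (robust to unequal
variances) on literature-report counts of core vs non-core nodes, with the
fold change of group means. Degenerate zero-variance inputs return p = 0
when the means differ and p = 1 when equal, with a warning.

## Small-world and scale-free characterization

σ = (C/C_rand)/(L/L_rand) with C the mean local clustering coefficient
(degree-<2 nodes contribute 0), L the mean shortest-path length over pairs
of the largest connected component (computed via sparse BFS), and the null
an ensemble (default n = 100) of G(n, M) graphs matched on node and edge
counts. Disconnected null members fall back to their largest component,
logged. The degree exponent γ is the continuous maximum-likelihood (Hill)
estimate with k_min chosen by KS minimization; a least-squares log–log
histogram slope is reported in parallel for plotting parity with the
familiar frequency-vs-degree curve. The MLE is the defensible estimate;
the slope is descriptive only.

## Markov clustering

MCL is implemented from its definition: column-stochastic matrix from the
adjacency with unit self-loops, iterate expansion (matrix power, default 2)
and inflation (entrywise power, default 2.0, then column renormalization),
pruning entries < 1e-5 as a numerical economy, until the maximum entrywise
change < 1e-6. Clusters are attractor systems of the limit matrix; nodes
with support on several attractors join the one holding their largest value
(ties → lowest id, logged). The procedure is deterministic. Clustering uses
binary adjacency by default (`weighted=True` applies combined scores).

Inflation is MCL's granularity dial. The package default 2.0 is the
canonical choice for PPI networks; the planted-block validation runs use
1.8 because at the validation scale (six 30-node blocks, mean degree ~10)
2.0 fragments block-sized modules — matching granularity to the expected
module scale is standard MCL practice, not a tuned constant. Modules below
the size cutoff (default 5) are flagged rather than deleted; kept modules
are ranked by size. Module ids are size-ranked and carry no correspondence
to any externally published module numbering. The meta-network counts
inter-module edges among kept modules; intra-module and
outside-kept-module edges are tallied separately so the three groups
partition |E| exactly (checked as an invariant).

## Enrichment

Fisher's exact test is computed from the hypergeometric mass: the two-sided
p sums the point probabilities of all tables with the observed margins that
are no more likely than the observed table (minimum-likelihood rule, the
common convention; tolerance 1e-9 relative on the tie comparison). A
one-sided upper-tail variant is available since enrichment is directional
in spirit. Odds ratios apply a 0.5 continuity correction when any cell is
zero, flagged on the record. Network-level enrichment uses a configurable
gene universe (default 20,000 protein-coding genes); rich-club enrichment
uses the network's node set as background. Raw p-values are primary;
Benjamini–Hochberg FDR is appended. The reported "enrichment score" is
−log10(raw p) — a display convention, labeled as such.

## Synthetic data and what it does (not) show

The generator emulates the statistical signatures of a curated disease
interactome at two scales: desk scale (500 nodes, preferential attachment
m = 5) and interactome scale (886 nodes, m = 20, ≈17,400 edges). Planted
features and their defaults:

- **rich-club core** — the 20 (desk) or 30 (full) highest-degree nodes
  densified to internal density 0.8 by adding missing internal edges;
  random-placement planting is available as a negative control where
  detection should fail;
- **block modules** — stochastic block model (p_in = 0.3, p_out = 0.01,
  six 30-node blocks in validation runs);
- **literature frequency** — Poisson counts, mean 20 reports for ordinary
  nodes and 4 × 20 for nodes above the 0.95 degree quantile. A four-fold
  step on hubs was chosen over a percentile-linear ramp deliberately: a
  linear ramp spreads the elevation over the whole network and caps the
  recoverable club/non-club fold near 1.6 regardless of the planted factor,
  so it cannot represent a four-fold club effect as a recoverable ground
  truth;
- **drugs** — target sets of 40–120 nodes drawn without replacement with
  probability ∝ degree^2 (hub-biased) or uniformly, in matched pairs.

Edge "combined scores" are uniform draws on [0.4, 1]; no attempt is made to
mimic STRING's score distribution. All generators are pure functions of
their parameters including the seed, and every planted feature is returned
as machine-readable ground truth that analysis code never reads.

What passing the recovery tests shows: the pipeline detects the planted
structures at realistic sizes and effect magnitudes, with a calibrated null
(mean ρ ≈ 1 when nothing is planted). What it does not show: performance on
real interactomes with literature ascertainment bias, false-positive
interactions, score-dependent confidence structure, or overlapping
pathway membership — none of which the generator models. Preferential
attachment also yields less clustering than real PPI networks, so σ on the
synthetic preset (~2.3) is lower than values reported for curated
interactomes; the Watts–Strogatz validation case covers the high-σ regime
instead.

## Validation scales and numerical choices

Validation runs use sizes chosen to exercise each property convincingly at
desk scale: 50 random graphs ≤ 30 nodes for exact φ equivalence; a
500-node configuration-model graph with a 100-member ensemble for null
calibration; 20 replicates with 50-member ensembles for planted-core
recovery; all ≤ 12-node graphs against a literal MCL oracle; exhaustive
Fisher enumeration for all margins ≤ 40 (≈ 494,000 tables, agreement within
1e-10); 1,000-node graphs for the small-world checks. Determinism is
byte-level: identical config + seed reproduce identical artifacts (the
manifest's wall-times are the only run-varying output). Seeds for ensembles
and generators derive from a master seed via seed-sequence spawning, so no
result depends on evaluation order.

## Known limitations

- Degree-preserving rewiring approximates uniform sampling of simple
  graphs with fixed degrees; mixing is heuristic (10 swaps/edge, with an
  edge-overlap check in the tests) and no formal mixing diagnostics are
  run.
- φ undefined at the top thresholds means the significant range can never
  extend to the maximum degree; interpretation should use the core rule,
  not the raw range end.
- The plateau cutoff (φ ≥ 0.95) for the strongest component is a fixed
  convention; graphs whose φ saturates below it report an empty strongest
  component.
- Weighted rich-club and directed variants are out of scope.
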