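# Methods

This note documents the models and procedures implemented in
`antplantnet`, the defaults that matter, and the choices made where the
design was genuinely open.

## Data contract

The central object is a labeled plant × ant matrix of non-negative integer
visit counts. Counts are interaction frequencies over repeated censuses,
so files containing decimals are rejected rather than rounded, duplicate
labels within a guild are errors, and validation guarantees no all-zero
row or column. Plants are canonically rows (the lower trophic level);
files stored ants-as-rows are transposed at read time. Label matching is
exact after whitespace trimming — fuzzy matching would hide data errors.

The rare-interaction filter zeroes cells below a threshold (default 3
visits) and drops species left without links. Its purpose is statistical:
a species recorded once or twice cannot be distinguished from a rare
passer-by, and keeping it inflates apparent specialization, nestedness and
strength asymmetry.

## Network-level indices

**NODF.** For every unordered within-guild pair, the member with strictly
larger degree is "hi"; the pair scores 100 × (shared partners)/(degree of
lo), and equal-degree pairs score 0 (the decreasing-fill condition of the
strict metric, not the lenient variant). Row-pair and column-pair scores
are averaged together. The weighted variant keeps the binary-degree gate
and scores the fraction of the poorer species' occupied cells whose count
is strictly below the richer one's — the semantics of the reference
implementation (`vegan::nestednodf(weighted=TRUE)`), against which the
binary and weighted forms are cross-checked in the test suite.

**Dependence and asymmetry.** A plant's dependence on an ant is the
fraction of the plant's total visits contributed by that ant, and vice
versa. Per-link asymmetry is the absolute difference of the two
dependences normalized by the larger one (the per-link normalization; the
Blüthgen-corrected variant is a candidate extension but is not used in the
pipeline). The network value is the mean over realized links.

**Horn overlap** uses natural logarithms with the 2·ln 2 normalizer, which
bounds the index in [0, 1]; it is computed on proportion profiles and is
therefore invariant to rescaling any species' counts.

## Null model and Monte-Carlo tests

The null ("Ce", Null Model II) draws each cell as an independent Bernoulli
with probability equal to the mean of the row and column fill fractions of
the binarized observed matrix; expected fill equals observed fill exactly.
Draws with an empty row or column are rejected and redrawn (bounded at
10⁴ attempts) so every null network has the observed dimensions — the
alternative of keeping degenerate draws changes the null mean and was
rejected for comparability. p-values use the add-one convention
(#{null ≥ observed}+1)/(n+1), so they are never zero; the nestedness test
is one-sided (greater) because nestedness above null is the hypothesis of
interest. Replicate seeds are spawned from one root via `SeedSequence`, so
ensembles are reproducible and parallelizable.

## Modularity

Barber's bipartite modularity is computed on the binarized matrix (the
metric is defined on binary degrees; a weighted variant would be a
different estimator). The optimizer anneals single-species relocation
moves — moving one plant or ant to an existing or a fresh module — with
Metropolis acceptance exp(ΔQ/T) and geometric cooling. Defaults: T₀ = 1,
cooling 0.95, 2(P+A)² proposals per temperature, T_min = 10⁻⁴, three
independent restarts, each followed by a greedy polish (best single-move
sweeps to a local optimum); the best partition ever visited is returned
with empty modules compacted. Merge/split proposals were omitted: on all
≤10-species networks tested the relocation move set reaches the exhaustive
optimum (the suite asserts this against a full set-partition enumeration),
and the greedy polish removes the residual risk of returning a near-miss.
The move evaluation is incremental (O(degree) per proposal) via per-module
link counts and degree sums; the returned score is recomputed from the
assignment to eliminate accumulation drift.

Significance re-optimizes Ce null matrices with a reduced budget (T₀ =
0.25, cooling 0.85, 600 proposals per temperature, one restart plus
polish). A reduced budget slightly underestimates null Q_B, which makes
the test anti-conservative in principle; the greedy polish keeps the gap
small (null replicates at the reduced budget match full-budget scores to
within ~0.01 on study-scale networks), and the planted-partition and
random-network calibration tests bound the practical error.

## Species-level metrics

Strength sums the opposite guild's dependences on the species, so guild
totals conserve exactly (Σ ant strengths = number of plants); the suite
asserts this to machine precision. d′ standardizes the Kullback–Leibler
divergence of a species' partner-use proportions from partner availability
(marginal totals over the grand total) between the extremes attainable
with the species' integer visit total: the minimum by largest-remainder
allocation proportional to availability, the maximum by packing visits
into the scarcest partners first, each bounded by the partner's marginal
total. When no discrimination is possible (d_max = d_min) d′ is 0.
Core–periphery standardizes binary degree within the guild with the
sample standard deviation (n−1); species at Gc ≥ 1 (ties included) are
core. Binary rather than weighted degree is used because the underlying
formula is defined on numbers of links.

## Ordination and attribute fitting

Plants are the ordinated observations; their partner-use count vectors are
square-root transformed and Wisconsin-standardized when the matrix maximum
exceeds 9 (the usual community-ecology auto-transform; toggleable), then
converted to Bray–Curtis dissimilarities. NMDS alternates monotone
regression (pool-adjacent-violators, ties averaged) of configuration
distances on the dissimilarities with a Guttman update; disparities are
rescaled to the configuration's sum of squares for the update step to
prevent collapse, while stress-1 is evaluated on the raw isotonic fit. An
iteration that fails to decrease stress is rolled back, so the recorded
trace is non-increasing by construction. Start 0 is the classical-scaling
configuration, the remaining 19 (default) are random; the best start is
returned centered and rotated to principal axes with a deterministic sign
convention, and convergence is declared when a second start matches the
best within Procrustes error 10⁻³. Ants are placed at the
interaction-weight-weighted average of their plants' coordinates.

`envfit` scores a factor as 1 − SS_within/SS_total of the 2-D coordinates
about level centroids and a vector as the R² of the best linear
combination of axes predicting the variable; significance is the add-one
fraction of row permutations reaching the observed r². Factors and
vectors for each guild are fitted on that guild's own scores (plant
attributes on plant scores, ant attributes on weighted-average ant
scores); fitting one guild's attributes to a joint configuration is not
defined here. The mixed-habitat level "B" is excluded from the
open-vs-shaded contrast by default, because the contrast of interest is
between the two physiognomies.

## Synthetic data

The generator emulates the study system the package targets: a 31 × 19
community, visit counts averaging ~8 per realized link (zero-truncated
Poisson), a nested backbone from geometrically decaying species activities
(decay rate 2.5 across each guild), an open/shaded habitat label per
species with the odds of realizing a link multiplied by `habitat_effect`
(default 8) when the two species share a habitat, ant head lengths drawn
from a Gaussian copula on degree ranks targeting Spearman ρ = 0.565
(lognormal margin, median 1 mm), and a plant cover covariate drawn
independently of everything — the null "abundance" effect. The base link
rate is solved by bisection so the expected fill is 0.27 regardless of the
habitat boost, keeping connectance at the study scale. Any species left
unconnected receives one partner drawn by opposite-guild activity, so
generated matrices always satisfy the data contract.

What the generator does *not* emulate: sampling effort and detectability
(counts are exact draws, not censuses), seasonal turnover, phylogenetic
signal in partner choice, and any dependence between attributes beyond the
head-length–degree link. Passing tests therefore demonstrate that the
estimators recover known structure of this generative family, not that the
field data meet its assumptions.

A separate planted-partition generator (blocks with high within- and low
between-block link probability) provides ground truth for modularity.

## Problem sizes and numerical choices

Monte-Carlo defaults are 1000 replicates for nestedness and attribute
permutations and 200 re-optimized replicates for modularity significance;
the test suite and the acceptance script use these at study scale and
smaller ensembles on reduced networks where many replicates are needed
(e.g. 200-replicate type-I calibration on 20 × 12 networks, 100-replicate
power runs at 30 × 20). Brute-force modularity enumeration is bounded at
10 species (set-partition counts grow super-exponentially). Permutation
p-values are never 0 by the add-one rule; ties in isotonic regression are
averaged; equal-degree NODF pairs and equal-total d′ extremes resolve to 0
by the definitions above.

## Known limitations

- The weighted-nestedness estimator is WNODF; other weighted nestedness
  measures (e.g. WINE) are different statistics and not provided.
- The reduced null-ensemble annealing budget trades a small downward bias
  in null Q_B for tractability (see above).
- NMDS minimizes stress-1 with a primary/averaged tie treatment; runs are
  deterministic under a seed but, as with any NMDS, different starts can
  reach distinct local optima — the multi-start design and convergence
  flag mitigate, not eliminate, this.
- envfit's permutation test assumes exchangeable rows; it does not account
  for phylogenetic or spatial autocorrelation among species.
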