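# antplantnet

Quantitative analysis of ant–plant mutualistic interaction networks.

Communities of plants bearing extrafloral nectaries (EFNs) and the ants
that visit them form weighted bipartite networks: a plant × ant matrix of
visit counts accumulated over repeated censuses. Community ecologists ask
whether such a network is *nested* (specialists interacting with subsets of
the generalists' partners), whether it is *modular* (cohesive plant–ant
compartments), which species form its generalist *core*, and which species
or habitat attributes — EFN morphology, plant cover, vegetation structure,
ant body size, behavioral dominance, invasiveness — explain the pattern of
pairwise interaction frequencies. This package implements that complete
workflow for a weighted interaction matrix plus per-guild attribute tables.

## What it computes

For a matrix with `P` plants, `A` ants, `L` links and total frequency `F`
(cells `w_ij`, binary degrees `k_i`, `d_j`):

- **Network level** — connectance `L/(P·A)`; NODF nestedness (paired
  overlap with decreasing fill, 0–100) and its weighted variant WNODF;
  dependence asymmetry (mean over links of `|d_plant − d_ant| /
  max(d_plant, d_ant)` where `d_plant = w_ij/Σ_j w_ij`); mean Horn niche
  overlap within each guild.
- **Null model** — the degree-proportional Bernoulli null ("Ce" / Null
  Model II, `p_ij = (k_i/A + k_j/P)/2`) with Monte-Carlo significance for
  any scalar statistic (add-one p-values, degenerate draws rejected).
- **Modularity** — Barber bipartite modularity
  `Q_B = (1/F) Σ_ij (B_ij − k_i d_j/F) δ(g_i, g_j)` maximized by simulated
  annealing with single-species relocation moves, plus an exhaustive
  oracle for tiny networks and null-ensemble significance.
- **Species level** — degree; species strength (summed dependence of the
  opposite guild); the d′ specialization index (standardized
  Kullback–Leibler divergence of partner use from availability);
  core–periphery scores `Gc = (k − mean k)/sd k` with core at `Gc ≥ 1`.
- **Ordination** — Bray–Curtis dissimilarities (with the usual
  square-root + Wisconsin auto-transform for large counts), 2-D non-metric
  multidimensional scaling minimizing Kruskal stress-1 over multiple
  starts, weighted-average scores for the second guild, and permutation
  `envfit` of categorical factors and continuous vectors onto the
  ordination.
- **Classic tests** — Spearman rank correlation, χ² goodness of fit,
  one-way ANOVA, Sorensen similarity.
- **Synthetic data** — a generator producing study-scale networks with a
  nested backbone, an open/shaded habitat block signal, head lengths
  correlated with ant degree, and an independent (null) abundance
  covariate, so every stage can be validated on data of known truth.

## Worked example

```python
from antplantnet import connectance, nodf, null_test, run_pipeline
from antplantnet.pipeline_cli import PipelineConfig
from antplantnet.synthetic_data import SyntheticConfig, generate_network

matrix, plants, ants = generate_network(SyntheticConfig(rng_seed=5))
report = run_pipeline(matrix, plants, ants,
                      PipelineConfig(min_count=None, n_reps_nestedness=200,
                                     n_reps_modularity=50, rng_seed=11))
```

On this synthetic community the pipeline prints (via `log=`):

```
[input] 31x19, L=174, F=1389
[nestedness] NODF=48.65 null=36.67 p=0.004975 (0.2s)
[modularity] Q_B=0.315 modules=4 p=0.0196 (31.0s)
[core] 6 core plants, 4 core ants
[ordination] stress=0.219 (best start 4, 1.5s)
[spearman] head length vs ant degree rs=0.680 p=0.00136
```

Reading: the network is far more nested than its degree-proportional null
(NODF 48.7 vs 36.7, p < 0.01); the habitat block signal induces mild but
detectable modularity; a handful of generalists form the core; the 2-D
ordination is interpretable (stress ≈ 0.22); and larger-headed ants visit
more plant species (rs = 0.68), all mirroring the structure the generator
plants. The attribute fit on the same run gives habitat r² = 0.39
(p = 0.002) while EFN type and cover are non-significant — the habitat
signal, not abundance, structures the pairwise interactions.

The same analysis is available from the shell:

```sh
antplantnet simulate --preset habitat --seed 1 --out-dir demo
antplantnet analyze demo/matrix.csv --plants demo/plant_attributes.csv \
    --ants demo/ant_attributes.csv --seed 42 --out-dir demo_report
```

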