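# ecoassembly

Phylogenetic null models, cohesion and constrained ordination for microbial
community ecology along environmental gradients.

## The problem

16S amplicon surveys along an estuarine salinity gradient (or any strong
environmental gradient) pose three linked questions:

1. **Which assembly processes structure the communities?**  For every pair of
   samples the abundance-weighted β mean-nearest-taxon distance,

   βMNTD(k, m) = ½ [ Σ_{i∈k} f_ik · min_{j∈m} d(i, j) + Σ_{j∈m} f_jm · min_{i∈k} d(j, i) ],

   is compared with a null distribution obtained by shuffling taxa (names and
   abundances together) across the tips of the phylogeny.  The z-score βNTI =
   (βMNTD_obs − μ_null)/σ_null flags deterministic selection: βNTI < −2
   homogeneous selection, βNTI > +2 variable selection.  Pairs inside ±2 are
   ranked by the Raup–Crick score on Bray–Curtis (RC_Bray ∈ [−1, 1]) against a
   probabilistic null that reassembles each sample at its observed richness
   and depth from the regional occupancy and abundance pools: RC > 0.95
   dispersal limitation, RC < −0.95 homogenizing dispersal, otherwise drift.
2. **How strongly do taxa co-occur?**  Cohesion sums, per sample, the
   abundance-weighted connectedness of its taxa, where connectedness is a
   taxon's mean positive (or negative) pairwise correlation after subtracting
   the expectation under a taxa-shuffle null — positive cohesion in [0, 1],
   negative in [−1, 0].
3. **What explains the β-diversity?**  PERMANOVA (sequential McArdle–Anderson
   sums of squares), distance-based RDA on Cailliez-corrected principal
   coordinates with Ezekiel-adjusted R², VIF pruning of collinear predictors,
   and variance partitioning of adjusted R² among predictor groups
   (salinity, temperature, organic matter / nutrients, cohesion).

Because the statistics are null-model based, the package ships a first-class
synthetic-community generator — Yule trees, Brownian niche traits, Gaussian
environmental filters, ecological drift, planted co-occurrence factors, and a
full 9-station × 5-date × {free-living, particle-attached} estuary design —
so every inference stage is validated by parameter recovery against known
truth.

## A worked example

```python
from ecoassembly import (ScenarioConfig, simulate_scenario,
                         quantify_assembly, summarize_processes)

table, tree, traits = simulate_scenario(
    ScenarioConfig(process="variable_selection", n_taxa=120,
                   n_samples=12, depth=3000, seed=4))
pairs = quantify_assembly(table, tree, n_null=299, seed=11)
print(summarize_processes(pairs).round(3))
```

prints (one row per group, fractions over the five process labels):

```
       n_pairs  n_degenerate  variable_selection  homogeneous_selection  homogenizing_dispersal  dispersal_limitation  undominated
group
all         66             0               0.545                  0.091                   0.106                   0.0        0.258
```

The 12 samples sit in two blocks of 6 with well-separated niche optima.  The
36 cross-block pairs (36/66 = 0.545) are detected as variable selection —
more phylogenetically dissimilar than chance — while the within-block pairs,
which share an optimum, fall to homogeneous selection or the stochastic
labels: exactly the structure the generator planted.  The `examples/` directory has one short script per capability
(simulation, α/β-diversity, assembly processes, cohesion, constrained
ordination, full pipeline), each printing what its numbers mean.

A thin CLI wraps the two shell-level entry points:

```bash
ecoassembly simulate --out sim/ --seed 7
ecoassembly run --config run.toml --out results/
```

`run` executes the whole analysis graph (filters → diversity → ordination →
assembly processes → cohesion → dbRDA/varpart → FL–PA dissimilarity → RDA)
and writes every stage's output plus a manifest of config, versions and
output hashes that reproduces the run bit-for-bit.

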