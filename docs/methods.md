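# Methods

This note documents the models implemented in `ecoassembly`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the literature is silent.

## Diversity metrics

*Richness* counts taxa with abundance > 0.  *Shannon entropy* is −Σ p ln p in
nats over within-sample proportions (scale-invariant, so counts or relative
abundances are both accepted).  *Faith's PD* is rooted: the branch set spans
the present tips **and the path to the root**, so the PD of the full
community equals the tree's total branch length.  An empty sample yields
(0, 0, 0) with a warning rather than an error, because empty samples are a
data-quality event, not a programming error.

*Bray–Curtis* is computed on total-sum-scaled rows only (the constructor
enforces row sums of 1); passing raw counts is an error by design, so no
silent renormalisation can change results between callers.

*βMNTD* between samples k and m is the abundance-weighted mean distance from
each taxon to its nearest relative in the other sample, averaged over both
directions (½ · [Σ f_ik · min_j d(i,j) + Σ f_jm · min_i d(j,i)]).  A taxon
present in both samples is its own nearest relative (distance 0), which makes
βMNTD(k, k) = 0.  The implementation computes, per sample m, the vector of
minimum distances from every taxon to m's members; all pair values then
follow from one matrix product.  A brute-force double loop over taxon pairs
serves as the test oracle (agreement to 1e-10).

## Assembly-process inference

**βNTI.**  Each null iteration draws one uniform permutation of the
taxon↔tip assignment (topology and branch lengths fixed; names and
abundances move together) and recomputes βMNTD for *all* pairs from the
permuted patristic lookup — one shared permutation stream per analysis,
seeded, so serial and repeated runs agree.  βNTI is the z-score of the
observed value against the 999-draw null (population SD).  Pairs whose null
distribution has zero spread (e.g. identical communities, or distance-
constant star trees) are flagged *degenerate*: βNTI is reported as 0 when
the observation equals the constant null and ±∞ otherwise, and such pairs
are excluded from process fractions.  Thresholds are strict (> 2, < −2);
values exactly at a threshold fall through to the next rule.

**RC_Bray.**  For each sample the null model assembles 999 communities that
preserve its observed richness and read depth: taxa are drawn without
replacement with probability proportional to regional occupancy (fraction of
samples occupied, over the full input table), each drawn taxon receives one
read, and the remaining reads are assigned multinomially with probability
proportional to regional relative abundance among the drawn taxa.  The score
is the rescaled rank of the observed Bray–Curtis within the null,
2·([#(null < obs) + ½·#(null ≈ obs)]/999 − ½), with ties (|Δ| ≤ 1e−12)
taking half weight.  Null assemblages are generated once per *sample* from a
substream keyed on (seed, sample index) and reused across that sample's
pairs — the null distribution is identical to per-pair generation, at half
the cost, and results are independent of pair evaluation order.  The
regional pool defaults to all samples in the analysis set; restrict the
input table to restrict the pool.

**Classification** is the standard five-way rule: βNTI > 2 variable
selection; βNTI < −2 homogeneous selection; otherwise RC > 0.95 dispersal
limitation, RC < −0.95 homogenizing dispersal, else undominated.  Group
summaries report fractions over classified (non-degenerate) pairs, which sum
to 1 per group.

### Detection limits at reduced pool size

The test suite validates process recovery on 200-taxon pools (20 samples,
depth 5000, 999 nulls) so it runs in seconds.  Two regimes recover cleanly
at this scale: neutral simulations give |βNTI| ≤ 2 for ~95–99 % of pairs,
and variable-selection simulations give βNTI > 2 for essentially all
cross-block pairs.  The homogeneous-selection regime is different in kind:
because βMNTD ≥ 0, βNTI is bounded below by −μ_null/σ_null, and with only
tens of occupied tips on a 200-tip tree the tip-shuffle null's coefficient
of variation does not fall below ≈ 0.2 (the permuted positions of the
partner community — its "scaffold" — are shared randomness that does not
self-average at this size).  Even perfectly clade-confined communities
therefore top out around 60–95 % of pairs below −2 depending on the tree
realization, versus the near-total dominance reported from surveys with
~10⁴ taxa and ~10³-taxon samples, where the null self-averages.  This is a
property of the statistic at reduced scale, not of the implementation; the
recovery test keeps the full-strength ≥ 90 % requirement and is expected to
fail for some tree seeds.

## Cohesion

Pipeline: read-count prefilter (taxa with fewer than 150 reads across all
samples removed; taxa exactly at the threshold kept) → persistence filter
(taxa present, count > 0, in ≥ 10 % of samples) → total-sum scaling →
pairwise Pearson correlations → taxa-shuffle null (200 iterations; each
taxon's abundance vector permuted independently across samples; expected
correlation = mean over iterations) → connectedness (per taxon, the mean of
strictly positive and of strictly negative corrected correlations, with the
signed-subset size as denominator; 0 if the subset is empty) → cohesion
(per sample, abundance-weighted sum of connectedness).

Numerical choices: corrected correlations (observed − expected) are clipped
to [−1, 1], which guarantees positive cohesion ∈ [0, 1] and negative
cohesion ∈ [−1, 0] on every input; since expected correlations are near
zero, the clip is inactive on realistic data.  Constant abundance vectors
have undefined Pearson r; their correlations are set to 0 with a warning.
The taxa-shuffle uses one substream per taxon keyed on the taxon id, so the
expected matrix is exactly invariant to taxon ordering.  Correlations are
computed on relative abundances after filtering; the provenance dictionary
records every knob.

A calibration caveat: on tables whose taxa are truly independent, corrected
correlations retain the Pearson sampling noise (SD ≈ 1/√(n−1)), so the
signed-subset means — and hence cohesion — have a noise floor of
≈ 0.8/√(n−1) (≈ 0.15 at 30 samples).  Cohesion magnitudes are therefore
comparable only across samples of the same survey, not across studies with
different sample counts.  What the null correction does remove is the
spurious correlation structure induced by skewed abundance distributions.

## Ordination and variance partitioning

**PCoA** Gower-centers −½D² and eigendecomposes.  The **Cailliez constant**
is the smallest additive constant on off-diagonal distances making the
configuration Euclidean, computed as the largest real eigenvalue of the
standard 2n×2n companion matrix; the implementation was verified against
R's `ape::pcoa` on a non-Euclidean Bray–Curtis fixture (agreement to the
printed 15 digits).  Axes with eigenvalues ≤ 1e−8·max|λ| are dropped;
variance proportions are over the retained positive eigenvalues.

**PERMANOVA** uses McArdle–Anderson trace identities with sequential
(Type-I) sums of squares in the caller's term order; factors are dummy-coded
and rank is tracked through an orthonormal basis, so aliased terms are
detected.  p-values use unrestricted permutation of the Gower-centered
matrix and the (1 + exceedances)/(1 + n_perm) estimator, hence p > 0 always.
When the residual SS is numerically zero (perfect separation) the pseudo-F
is +∞; permutations that reproduce the partition legitimately tie.
Single-factor pseudo-F agrees with scikit-bio's permanova to 1e−10.

**betadisper** embeds via Cailliez-corrected PCoA (all axes real), measures
each sample's distance to its group centroid (centroid variant; the spatial-
median variant is not implemented), and tests group equality of mean
dispersion with a permutation F test.  Singleton groups are excluded with a
warning; all-identical inputs are reported degenerate.

**VIF pruning** z-scores the predictors and iteratively removes the largest
variance-inflation factor until all are below 10 (perfectly collinear
predictors sort first via an infinite-VIF sentinel).

**dbRDA** regresses *all* positive Cailliez-PCoA axes (total inertia
preserved, no truncation) on z-scored predictors; **RDA** does the same with
z-scored numeric responses.  R² is constrained SS over total SS; adjusted R²
uses the Ezekiel formula 1 − (1 − R²)(n − 1)/(n − m − 1) with m the rank of
the predictor matrix.  The overall test permutes response rows; per-axis
tests compare each constrained eigenvalue with its permutation distribution
(a deliberately simple scheme — the marginal sequential-axis construction
used by some R implementations is not reproduced, so per-axis p-values are
comparable within a model but not across packages).

**Variance partitioning** fits a dbRDA for every non-empty union of the 2–4
predictor groups and solves the inclusion–exclusion system
f(S) = Σ_{cells C: C∩S ≠ ∅} cell(C) for the Venn cells, so the cells sum to
the full-model adjusted R² by construction (residual = 1 − total).  Negative
cells are retained in machine output; display layers may suppress them.

## Synthetic communities

The generators exist to make the inference stages testable by parameter
recovery; they are pure functions of (config, seed).

*Trees* are pure-birth (Yule, rate 1) with exponential waiting times, tips
extended by one extra waiting time, rescaled to unit height so trait and
filter scales are comparable across taxon counts.  *Niche traits* evolve by
Brownian motion (child = parent + N(0, σ_BM²·branch length)); on the
unit-height tree the marginal tip SD is σ_BM, and trait similarity decays
with patristic distance — the phylogenetic signal the βMNTD framework
assumes.

*Selection communities* draw reads multinomially with
p_i ∝ a_i · exp(−(trait_i − E)²/(2σ_f²)), where a_i are log-normal
metacommunity abundances and σ_f is the niche breadth (environmental units).
Optional ecological drift adds the between-sample turnover real communities
have: per-sample Bernoulli local extinction (probability 0.3 in scenarios)
and log-normal abundance noise (log-SD 0.4), plus an optional hard
physiological range at 2.5 σ_f.  These default to **off** at the function
level (the pure filter limit behaviours hold exactly) and **on** in
`ScenarioConfig`, because without turnover all abundance sits on shared
taxa, which contribute zero to observed and null βMNTD alike, and no
scenario has any β-diversity to classify.  Scenario metacommunities use
log-SD 0.3 (high evenness, as in real amplicon surveys at comparable
richness); the stand-alone `metacommunity_abundances` keeps log-SD 1 for a
realistic rank-abundance curve.

For the homogeneous-selection scenario the common optimum is, by default,
placed where the trait window is phylogenetically most coherent (scored by
the window's mean nearest-taxon distance relative to random sets of the same
size, over trait quantiles and a grid of breadths).  Ecologically this says
the environment favors an actual clade — the conserved-niche premise under
which selection is detectable at all; with a 1-D Brownian trait an optimum
at an arbitrary value (e.g. the root state) selects convergent lineages from
across the tree and the scenario does not realize its named regime.

*Neutral communities* are multinomial draws from one metacommunity with the
same optional drift; *dispersal-limited communities* restrict each sample to
a random founder subset.  *plant_cooccurrence* multiplies group members'
abundances by exp(±λz) with one latent z ~ N(0, 1) per sample (antagonistic
groups load negatively), renormalises and redraws at the original depth —
per-sample depths are preserved exactly, and λ = 0 returns the input
unchanged.

*The estuary dataset* fixes the survey design: 9 stations at salinities
0–34 PSU × 5 dates × {FL, PA} = 90 samples.  Salinity niches are Brownian
(root 17 PSU, tip SD 12 PSU, breadth 4 PSU); an independent, non-conserved
thermal niche (breadth 6 °C) adds the seasonal signal; DIN and silicate
follow the conservative dilution line with ~8 % multiplicative noise
(Spearman ρ with salinity ≈ −0.94); phosphate peaks mid-estuary; suspended
particulate matter peaks in the maximum-turbidity zone (salinity ~5–10) and
in winter/spring; chlorophyll rises in summer.  PA communities reuse the FL
parameters with the selection weight of one particle-specialist clade
(~25 % of taxa) multiplied by e^1.5 — a single knob controlling FL–PA
dissimilarity (0 makes the fractions exchangeable).  A latent co-occurrence
factor (one positive and one antagonistic group of 15 taxa, λ = 0.5) gives
the cohesion stage signal.  A few taxa are labelled as chloroplast /
mitochondrial / archaeal contaminants to exercise the taxonomy filter.

What the generator does **not** emulate: sequencing error and chimeras
(taxa are abstract tips, not sequences), the mixing hydrodynamics of a real
estuary, FL↔PA exchange dynamics (the specialist skew is a static stand-in),
and the ~10⁴-taxon pool sizes of real surveys — so passing recovery tests
demonstrate correctness of the statistics, not field-scale effect sizes
(see the detection-limits section above).

## Pipeline and reproducibility

`run_pipeline` executes load/simulate → taxonomy filter (case-insensitive
rank/value patterns; default removes Eukaryota, Archaea, Chloroplast,
Mitochondria) → optional rarefaction (multivariate hypergeometric, samples
below depth dropped with a warning naming them) → α-diversity → total-sum
scaling → Bray–Curtis + βMNTD → PCoA/PERMANOVA/betadisper → assembly
processes per fraction → cohesion per fraction → dbRDA + variance partition
per fraction (predictor groups: salinity; temperature; SPM, %POM, Chl a,
DOP, phosphate; positive and |negative| cohesion) → FL–PA pairwise
dissimilarity per (station, date) → RDA of those dissimilarities.  Every
stage writes TSV/JSON; the manifest records the config, package version,
SHA-256 of every output and all collected warnings.  Randomness derives from
one global seed through stage-name-hashed substreams, so adding a stage
never perturbs earlier stages' draws, and identical configs reproduce every
output byte-for-byte.  Count tables are read from TSV in either orientation
(BIOM-style input is not supported; construct a `CountTable` from any
DataFrame instead).

Default problem sizes in the test-suite and acceptance script (200 taxa,
20–90 samples, depth 4000–5000, 999 nulls for the per-criterion checks;
150 taxa / depth 4000 / 299 nulls for the end-to-end estuary run) were
chosen so the full validation executes in minutes on one CPU while keeping
every null-model replicate count at its standard value where a criterion
depends on it.

## Known limitations

- Homogeneous-selection recovery and the independent-taxa cohesion floor
  are scale-limited as analysed above; both validation checks keep their
  full-strength thresholds rather than masking the limits.
- PERMANOVA supports unrestricted permutations only (no strata/blocks).
- Degenerate βNTI pairs are excluded from fractions rather than imputed.
- The Raup–Crick null assumes every analysed sample belongs to one regional
  pool; pool restriction is by subsetting the input, not a grouping option.
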