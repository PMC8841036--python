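# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of `microdepth`.

## Analysis procedures

**Rarefaction.** Each sample is subsampled without replacement to a common
depth by an exact multivariate-hypergeometric draw
(`numpy.random.Generator.multivariate_hypergeometric`, marginal method).
Samples below the target depth are dropped with a logged warning rather
than resampled with replacement. Rarefying a sample to its own total is
the identity.

**Abundance partition.** Rare/abundant status is assigned on
*dataset-total* relative abundance (ASV reads / grand total): rare below
1 × 10⁻⁴ (0.01%), abundant above 1 × 10⁻³ (0.1%), intermediate otherwise.
Per-sample rare proportions are (rare ASVs present)/(ASVs present) for
richness and (rare reads)/(sample reads) for abundance.

**Vertical enrichment.** Per ASV, a Kruskal–Wallis test of per-sample
relative abundance across the three layers, Benjamini–Hochberg FDR across
ASVs, default q < 0.05. Significant ASVs are assigned to the layer with
the highest mean relative abundance (S/M/D), otherwise U. The statistical
criterion behind "enriched" is a package convention — the test is
deliberately simple and configurable, and an optional per-time
stratification flag reproduces one-panel-per-occasion analyses. ASVs
constant across all samples score statistic 0, q 1. Ternary coordinates
are the per-layer mean relative abundances normalized to sum to 1.

**Alpha diversity.** Shannon entropy uses the natural logarithm, so
Pielou's J = H/ln S equals 1 exactly for a uniform community; J is flagged
undefined when S ≤ 1. The two-way ANOVA accepts only balanced designs
(equal replicates per layer × time cell), where Type I and Type III sums
of squares coincide; unbalanced input is rejected explicitly rather than
silently re-weighted. The post-hoc is Tukey HSD (studentized range), the
package's choice of pairwise procedure. Statsmodels (OLS + anova_lm) and
scipy (tukey_hsd) provide the fitting machinery; tests verify the SS
decomposition against a direct cell-mean computation to 1e-9.

**Fertility index.** Sum of z-scores (sample sd, ddof = 1) of TC, TN,
DOC, DON, NH₄⁺-N and NO₃⁻-N across all samples. The index is centred at
zero and invariant to affine rescaling of any input variable; a
zero-variance nutrient raises an error naming the variable.

**Random-forest drivers.** A regression forest (scikit-learn, default 500
trees, mtry = ⌈p/3⌉) is fit to the response; per-predictor importance is
the percent increase in training MSE when that predictor's column is
permuted (5 repeats, batched predictions). Significance refits the forest
on permuted responses: P = (1 + #{null importance ≥ observed}) /
(1 + n_perm). Under the null this P is exactly uniform on its support by
exchangeability of the (response, forest-seed) pairs. Predictors are
canonicalized by sorted column name internally, making results exactly
invariant to input column order at a fixed seed.

**Beta diversity.** Bray–Curtis, PCoA and PERMANOVA are implemented
directly on the distance matrix. PCoA eigendecomposes the Gower-centred
matrix G = −½ J D² J; coordinates use positive eigenvalues only, and
negative eigenvalues are reported rather than Lingoes/Cailliez-corrected
so the non-Euclidean share stays visible. PERMANOVA partitions tr(G)
sequentially (Type I) over the formula's terms via cumulative hat-matrix
traces tr(H G); pseudo-F compares term and residual mean squares, and P
comes from free permutation of sample labels (no plot-level restriction),
with a 1e-9 relative tie tolerance so permutations equivalent to the
identity count as ≥. r² = SS_term/SS_total sums to 1 with the residual by
construction. The Mantel statistic is the Pearson correlation of
strictly-upper-triangle entries with simultaneous row/column permutation
of the second matrix (one-sided, greater). Tests cross-check pseudo-F and
eigenvalues against scikit-bio and against exhaustive enumeration on
6-sample toys.

**Networks.** Per layer: ASVs with dataset-subset relative abundance
strictly above 0.5% and occurrence strictly above 50% of the layer's
samples enter a Spearman correlation matrix (average ranks, two-sided
t-approximation p, n − 2 df). P-values of the upper triangle are
BH-adjusted and edges are kept when |ρ| ≥ 0.8 **and** q ≤ 0.001 —
the absolute-value reading is required for negative links to exist at
all, and the q-gate (rather than raw p) reflects the FDR step preceding
elimination; a flag allows raw-p gating for sensitivity analysis.
"Connectedness" being ambiguous, both connectance 2E/(N(N−1)) and the
largest-component fraction are reported. Module detection is
Clauset–Newman–Moore greedy modularity maximization on the unweighted,
unsigned graph (networkx); the algorithm is deterministic, so the seed
argument exists only for interface stability. Zi is the within-module
degree z-score (population sd; defined as 0 when the module sd is 0 or
the module has < 3 nodes); Pi = 1 − Σ_t (k_it/k_i)². Role thresholds
default to Zi = 2.5 and Pi = 0.62, the usual module-role convention, and
any non-peripheral node is flagged a keystone candidate; the full role
breakdown is emitted so stricter keystone definitions remain recoverable.

**Function mapping.** Rules are (rank:name → group) pairs in a
two-column TSV, matched exactly and case-insensitively at the stated
rank; an ASV feeds every matching group with its full counts (no
normalization across groups), mirroring how trait databases multi-assign
taxa. The bundled rules file is a deliberate miniature covering the
functions the examples discuss (sulfate/iron respiration, nitrogen
fixation, phototrophy, cellulolysis, dark hydrogen oxidation, ...); it is
not a curated database and carries no claim of biological completeness.
Attribution percentages per group sum to 100 over contributing taxa at
the chosen rank; zero-read groups are flagged undefined.

## Synthetic-data model

`simulate_dataset` emulates a balanced 6 plots × 4 times × 3 layers
survey (72 samples). Per ASV j and sample s, the latent log-abundance is

```
log λ_sj = a_j + plot_pj + layer/time contrasts + module factors
           + fertility link + ε_sj
```

- **SAD**: a_j ~ Normal(0, sad_sigma), default sigma 2 — a long rare tail
  (with ≥ 2000 ASVs, rare ASVs outnumber abundant ones, the skew the
  rare-biosphere analysis assumes).
- **Layer/time shifts**: a designated fraction of ASVs (default 10%)
  receives a mean-zero log-fold contrast — ×f^(2/3) in its preferred
  layer, ×f^(−1/3) elsewhere — so the preferred layer sits exactly f-fold
  (default 4) above each other layer while no net latent mass moves into
  any one layer (a one-sided boost would perturb the compositional
  denominator of every other ASV in that layer). Shifts are planted on
  non-module ASVs with base relative abundance ≥ 1e-4: vertical structure
  is a property of the detectable community, and shifts on ASVs with
  expected counts ≪ 1 read would be invisible at any realistic library
  size. Time effects (default 0 = absent) work identically over sampling
  occasions.
- **Modules**: n_modules blocks of module_size ASVs (default 3 × 10)
  share a per-sample latent factor ~ Normal(0, 1.5) scaled by
  module_strength (default 0.9), giving within-block Spearman
  correlations above the 0.8 edge threshold. Members are placed at a
  target dataset fraction (default 1% each) — inside the abundant tail
  and above the 0.5% network filter, but not dominant enough for their
  shared fluctuations to swamp Bray–Curtis space.
- **Plot**: a Normal(0, 0.1) random intercept per (plot, ASV) supports
  the repeated-plots design without spatial modeling.
- **Fertility link**: a per-sample latent fertility factor follows the
  depth gradient; a designated ASV set (default 20) co-varies with it,
  and the six nutrient variables are coupled to the same factor.
- **Noise and counts**: ε_sj ~ Normal(0, 0.5) lognormal overdispersion
  (≈ 50% CV between replicate samples, typical of 16S surveys), then a
  multinomial draw of library_size reads per sample — compositional
  closure holds exactly and fold-change is the single effect-size unit.
- **Soil**: each variable gets per-layer means (nutrients and sand
  decline with depth; moisture, pH and clay increase) with 8% relative
  noise; clay/silt/sand are renormalized to sum to 100.
- **Taxonomy**: lineages are drawn from a fixed toy pool — dominant soil
  phyla for the abundant tail, designated rare phyla and partially
  unclassified lineages for the rare tail — so phylum summaries, the
  per-rank unclassified tallies and function mapping are exercised.

What the generator does **not** emulate: sequence-level error, chimeras,
taxonomically structured correlations, spatial autocorrelation between
plots, non-multinomial overdispersion of the counting process, or
realistic archaeal/bacterial compartment sizes. Passing tests therefore
demonstrate correctness and calibration of the statistical machinery
under a controlled compositional model, not performance guarantees on
real surveys.

## Validation benchmarks

The `benchmarks` module fixes desk-scale study conditions (500 ASVs,
libraries of 10k–50k reads) used by both the test suite and
`scripts/acceptance.py`:

- **Type-I calibration**: under the null backdrop (all planted effects,
  module factors, plot and fertility variance zero — exact
  exchangeability for free permutation), the PERMANOVA layer term is
  tested over 200 simulated datasets and the random-forest permutation P
  over 100 datasets × 2 predictors (the minimal admissible predictor set,
  keeping the binomial-interval check honest against within-dataset
  correlation); both rejection rates at α = 0.05 must fall in the exact
  central 95% binomial interval.
- **Recovery**: PERMANOVA power under the null backdrop plus a 4-fold
  depth shift on 10% of ASVs (50 replicates, layer P ≤ 0.01 and layer r²
  > time r²); layer-enrichment recovery at 8-fold with 8 samples per
  layer and a 50k library (mean fraction of planted ASVs assigned to
  their true layer over 10 datasets); module recovery as the fraction of
  20 seeds with adjusted Rand index ≥ 0.9 between detected and planted
  modules; and forest-driver recovery with a response equal to one
  predictor.

Problem sizes are chosen so the whole benchmark suite runs in a few
minutes on one CPU while keeping every check at the stated strictness.

## Numerical choices and degenerate inputs

- Permutation P-values use the add-one estimator (1 + exceedances)/(1 +
  n_perm), never zero.
- PERMANOVA counts permuted F ≥ observed with a 1e-9 relative tolerance
  (identity-equivalent relabelings must tie).
- Hat matrices come from rank-revealing QR; a term confounded with its
  predecessors (zero added rank → zero residual df) is an error, not a
  silent drop.
- PCoA treats eigenvalues below 1e-9 × max|λ| as zero.
- Constant ASVs get NaN correlation p-values and can never pass the edge
  gates; constant responses, zero-variance nutrients, all-zero samples
  and empty filters all raise named validation errors.
- Per-stage seeds derive from the global seed via `SeedSequence([seed,
  stage-index])`, so a stage re-run in isolation reproduces its
  in-pipeline output; all derived seeds stay below 2³¹.

## Limitations

Correlation-based networks on compositional data are biased toward
spurious negative association; compositionality-aware estimators
(SparCC/SPIEC-EASI) are out of scope, as are restricted permutation
schemes for the plot factor, PERMDISP, UniFrac (no trees), unbalanced
ANOVA, signed-modularity community detection, and random-graph null
models for network metrics. The bundled function rules are illustrative
only. The balanced-design requirement is strict by intent.
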