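# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that matter for reproducing a
run exactly.

## Ecoenzymatic stoichiometry vectors

Microbial investment in nutrient acquisition is summarised per sample from
four potential enzyme activities: β-1,4-glucosidase (BG, carbon),
β-1,4-N-acetylglucosaminidase plus leucine aminopeptidase (NAG + LAP,
nitrogen) and alkaline phosphatase (ALP, phosphorus). The sample maps to
the planar point x = ln(BG)/ln(ALP), y = ln(BG)/ln(NAG+LAP); the vector
length √(x² + y²) indexes relative C limitation and the angle
degrees(atan2(y, x)) indexes the N-vs-P balance, with 45° the neutral
line: below 45° the community invests relatively more in N acquisition
(N-limited), above in P acquisition.

Choices worth stating explicitly:

- **Length is a norm.** The length is the square root of the sum of squared
  log-ratios; without the radical "length" would not be a distance and
  would not scale linearly with the underlying investment ratios.
- **atan2 argument order.** Spreadsheet `ATAN2(x, y)` reverses the argument
  order of the mathematical convention. We compute `degrees(atan2(y, x))`,
  which makes angle > 45° equivalent to ALP investment exceeding NAG+LAP
  investment. A config switch (`atan2_order="spreadsheet"`) exposes the
  mirrored convention for sensitivity analysis; it reflects angles about
  the 45° diagonal.
- **Domain.** Log-ratios are only sign-stable when every grouped activity
  exceeds 1 in its assay units. Activities ≤ 1 are rejected rather than
  shifted by +1; shifting silently changes the statistic. All realistic
  activities in the μmol h⁻¹ range satisfy the constraint comfortably. A
  proportion-based variant (BG/(BG+NAG+LAP), BG/(BG+ALP)) is provided as
  `method="proportion"` for data where the log-ratio domain is a concern.
- **Per-sample first.** Vectors are computed per sample and then averaged
  within treatment; computing them on treatment-mean activities is
  possible through the same functions but is not the default, since the
  nonlinearity of the log-ratio makes the two differ slightly.
- Units are carried as opaque labels and never converted; all statistics
  here are dimension-agnostic.

Microbial biomass C/N/P is the chloroform fumigation–extraction flush
(fumigated minus non-fumigated extract concentration) divided by the
extraction efficiency kEC = 0.45, kEN = 0.54, kEP = 0.40. A negative flush
is returned as a negative biomass value, flagged to the caller, never
clipped — clipping would hide assay problems.

## Alpha diversity

Each kingdom's OTU table (ITS-derived fungi, 16S-derived bacteria) is
rarefied independently to the minimum per-sample depth, by seeded
multivariate-hypergeometric subsampling (without replacement). A single
rarefaction with a fixed seed (default 42) is the default, matching the
common single-table workflow; `rarefaction_repeats > 1` averages indices
over repeated draws instead. Indices: observed richness; bias-corrected
Chao1 S + F₁(F₁−1)/(2(F₂+1)); Shannon–Wiener with natural logarithm;
Simpson reported as Gini–Simpson 1 − Σp² by default (the `dominance` and
`inverse` variants are selectable, since published figures frequently do
not state which was used).

## Co-occurrence networks

Networks are built per treatment on that treatment's nine composite
samples, with fungal and bacterial taxa pooled into one table (one network
per stand). Filters: a taxon is retained when its mean relative abundance
(per-sample count / sample depth, then averaged) is ≥ 0.01% **and** it
occurs in ≥ 50% of the samples in scope. Spearman rank correlations are
computed over all retained pairs (average ranks for ties); an edge requires
|ρ| > 0.9 (strict) and p < 0.05, with weight ρ. Taxa left without any edge
are dropped from the node set.

- **p-values at n = 9.** The default is the two-sided t approximation
  t = ρ√((n−2)/(1−ρ²)); with nine observations this is approximate, so a
  permutation null (20,000 shared rank permutations, fixed internal
  generator) is available via `pvalue_method="permutation"`. No
  multiple-testing correction is applied by default (the thresholds are
  already extreme at n = 9); Benjamini–Hochberg is available.
- **Topology.** Average degree 2E/N; average path length is the mean
  unweighted shortest-path length over reachable ordered pairs
  (disconnected pairs excluded — the igraph convention, appropriate for
  fragmented thresholded networks); average clustering is the mean local
  clustering coefficient with degree-< 2 nodes contributing 0; modularity
  is Newman weighted modularity of a Louvain partition on |ρ| weights with
  a fixed seed (greedy agglomeration available). Louvain is seed-sensitive,
  hence the seed lives in the pipeline config.

## Group statistics

Per variable, a one-way fixed-effects ANOVA across the four stand types
(composite samples as replicates, n = 9 per treatment) computed from
explicit sums of squares, followed — only when the omnibus F is significant
at α (protected) — by Fisher LSD pairwise comparisons using the pooled
within-group mean square: groups differ when |mean difference| >
t(1−α/2, df_w)·√(MSW(1/nᵢ+1/nⱼ)). Letters are the maximal cliques of the
non-significance graph, ordered so the highest mean receives 'a'. PCA of
enzyme activities operates on the correlation matrix (activities are on
different scales); component signs are fixed by making each component's
largest-magnitude loading positive.

## PLS path modeling

The latent model connects mycorrhizal dominance, pH, soil nutrients
(TC, TN, TP, SOC, AN, AP), fungal diversity, bacterial diversity and
microbial biomass (MBC, MBN, MBP) to vector length and vector angle.
Estimation is the classical Lohmöller alternating algorithm with
reflective (mode A) blocks throughout and the path scheme as default
inner weighting (centroid and factorial available): standardized
indicators, equal initial weights, inner estimates from adjacent latent
scores, mode-A weight update as indicator–inner-estimate correlation,
iterated until the largest absolute outer-weight change is < 1e-6 (max 300
iterations; non-convergence is flagged on the results object, not raised).
Path coefficients are OLS of each endogenous score on its predecessors,
loadings are indicator–score correlations, communality the squared
loading, GoF = √(mean communality × mean R²). Indicators with loading
< 0.6 (strict) are pruned and the model refitted; in the default pipeline
run this typically removes weak diversity indicators.

- **Sign convention.** Each latent is aligned to correlate positively with
  the sum of its own standardized indicators, making fits deterministic;
  flipping an indicator's sign flips only signs, never magnitudes.
- **Dominance coding.** Stand type is categorical; the exogenous
  "mycorrhizal dominance" latent needs a numeric coding. The default is an
  AM-influence gradient Ps.P = 0, Ps.M = Up.M = 0.5, Up.P = 1, supplied as
  a config mapping because any such coding is a modelling decision and
  path signs/magnitudes depend on it.
- **Significance.** Path significance uses a percentile bootstrap
  (resample rows, refit, align replicate latent signs with the original
  loadings); p is twice the smaller tail proportion about zero, floored at
  1/(n_boot+1). With single indicators and indicator noise, PLS-PM path
  estimates are attenuated like correlations; bootstrap intervals cover the
  estimand, not the disattenuated coefficient.
- The pipeline default is 299 bootstrap replicates; the standalone API
  default is 999 (and n_boot < 100 is rejected as meaninglessly coarse).

Total effects of the acyclic path matrix B are Σ_{k≥1} Bᵏ — the sum over
all directed paths of products of coefficients; the series is finite for a
DAG.

## Synthetic data generator

The generator emulates the study design end to end: four stand treatments
(Ps.P, Up.P, Ps.M, Up.M), three 50 m × 50 m plots per stand, 15 standard
trees per plot pooled five-at-a-time into three composite rhizosphere
samples — nine samples per treatment, 36 in total.

- **Measurements** are independent truncated-at-zero normal draws per
  treatment. Default means and sds for soil chemistry are the published
  treatment summaries of the motivating study system (e.g. Up.M TC
  9.85 ± 0.18 g/kg); enzyme means use the printed group values where
  available (BG highest in Up.P at 29.60 μmol h⁻¹ and 1.94×/1.92× the
  mixed-stand values; NAG+LAP 71.49 in Ps.P; ALP 43.37/43.57 in the mixed
  stands) and are otherwise back-solved from the printed per-treatment
  vector length/angle pairs so that the default bundle reproduces the
  published orderings; the N pool is split 60/40 between NAG and LAP.
  Enzyme sds default to 5% CV (not published). Biomass means for the two
  unpublished treatments are set between the published minimum (Up.P) and
  maximum (Up.M) respecting the reported ordering (mixed > pure,
  EcM > AM pure). Truncation at zero is negligible at these CVs but
  guarantees validity; sd = 0 reproduces the means exactly (used by
  tests). Biomass is emitted as fumigation-extraction concentration pairs
  so the pipeline's conversion step is exercised.
- **Communities**: per sample, log-abundance of taxon i is
  μᵢ + δ_{i,treatment} + λ·f_{c(i)} + ε, with baseline spread μᵢ ~ N(0, 1.5),
  treatment shifts δ ~ N(0, 0.3), one standard-normal factor per planted
  clique scaled by λ = 2 for members, and residual ε ~ N(0, 0.5).
  Compositions are softmax(log-abundance); counts are multinomial at a
  depth drawn uniformly within the kingdom's realistic range (fungi
  67,329–78,875; bacteria 114,221–130,978 reads). The factor model is
  deliberately minimal: its only job is to plant recoverable rank
  correlations. It does not emulate taxonomy, phylogeny, compositional
  zero-inflation or sequencing error, so passing network-recovery tests
  demonstrates correctness of the inference chain, not performance on real
  amplicon data.
- **SEM data**: latents generated recursively from a strictly
  lower-triangular coefficient matrix with disturbance variances solved so
  every latent has unit variance — the coefficients are then exactly the
  standardized path coefficients. Indicators are (latent + σe)/√(1+σ²),
  standardized in expectation.

All generators are pure functions of (config, seed); per-sample rarefaction
streams are spawned from a SeedSequence so results are independent of
column order.

## Problem sizes and determinism

The default synthetic bundle uses 400 fungal and 800 bacterial taxa; the
test suite uses 30–90 taxa per kingdom, chosen so brute-force oracles
(all-pairs BFS, triangle counting, exhaustive set-partition modularity on
8 nodes, path enumeration over 5-latent DAGs) remain exact references.
Parameter-recovery checks use n = 10⁴ noise-free SEM samples; bootstrap
coverage is assessed at n = 200 with ~200 replicates. Two runs with the
same inputs, config and seeds produce byte-identical output files; this is
tested.

## Known limitations

- |ρ| > 0.9 with nine samples sits near the attainable extreme of the rank
  scale; edge sets are therefore sensitive to single-sample perturbations,
  and the t-approximate p-value is coarse at this n. This mirrors the
  workflow the package implements rather than a defect of it.
- Protected LSD controls pairwise error only through the omnibus gate; it
  is anti-conservative relative to Tukey HSD.
- PLS-PM standard errors come only from the bootstrap; no normal-theory
  covariance is provided. Results depend on the dominance coding, which is
  a declared config input.
- The compact-letter display is exact for the non-significance relation
  but not guaranteed minimal in letter count for adversarial patterns
  (maximal-clique ordering is used, which is minimal for the group counts
  that occur here).
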