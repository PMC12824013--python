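# ecostoichnet

Quantitative analysis pipeline for rhizosphere microbiome studies that
compare stands dominated by different tree mycorrhizal types (arbuscular
mycorrhizal *Ulmus pumila* vs. ectomycorrhizal *Pinus sylvestris* var.
*mongolica*, pure and mixed). It is aimed at soil ecologists who have
per-sample enzyme assays, soil chemistry, fumigation–extraction
measurements and OTU count tables, and want the full downstream analysis —
from microbial nutrient-limitation indices to co-occurrence network
topology and latent path modeling — as reproducible, tested code.

## What it computes

**Ecoenzymatic stoichiometry vectors.** Four extracellular enzymes index
microbial nutrient acquisition: BG (C), NAG + LAP (N), ALP (P). Each
sample's acquisition profile maps to the planar point

```
x = ln(BG) / ln(ALP),   y = ln(BG) / ln(NAG + LAP)
```

with vector length `sqrt(x² + y²)` quantifying microbial C limitation and
vector angle `degrees(atan2(y, x))` splitting N limitation (< 45°) from P
limitation (> 45°). Microbial biomass C/N/P comes from the chloroform
fumigation–extraction flush divided by kEC = 0.45, kEN = 0.54, kEP = 0.40.

**Alpha diversity.** Each kingdom's OTU table is rarefied (seeded
subsampling without replacement) to the minimum depth retaining all
samples, then summarised by observed richness, bias-corrected Chao1,
Shannon–Wiener (natural log) and Gini–Simpson indices.

**Co-occurrence networks.** Per treatment, taxa passing the mean relative
abundance (≥ 0.01%) and prevalence (≥ 50%) filters enter an all-pairs
Spearman correlation; pairs with |ρ| > 0.9 and p < 0.05 become undirected
weighted edges. Each network is summarised by node and edge counts, average
degree, average path length (reachable pairs), average clustering
coefficient, and modularity of a seeded Louvain partition on |ρ| weights.

**Group statistics.** One-way ANOVA per variable across the four stand
types with protected Fisher LSD compact-letter displays, plus PCA of the
enzyme activities.

**PLS path modeling.** A from-scratch Lohmöller-style PLS-PM
(mode A, centroid/factorial/path schemes) relating mycorrhizal dominance,
pH, soil nutrients, fungal and bacterial diversity, and microbial biomass
to the two limitation responses, with loading-based indicator pruning
(< 0.6), R² per endogenous latent, GoF = sqrt(mean communality × mean R²),
total (direct + indirect) effects, and a percentile bootstrap for path
significance. The model API is statsmodels-like: `PLSPathModel(...).fit()`
returns a `PLSPathResults` with `summary()`, `total_effects()`,
`bootstrap()`.

**Synthetic study bundles.** `ecostoichnet.simulate` generates the full
design (4 treatments × 3 plots × 3 composite samples), treatment-structured
measurements, OTU tables with planted co-occurrence cliques, and SEM data
with known coefficients, so every stage has a recoverable ground truth.

## Worked example

```python
from ecostoichnet import (
    SimulationConfig, generate_bundle, PipelineConfig, run_pipeline,
)

cfg = SimulationConfig(n_taxa={"fungi": 60, "bacteria": 90},
                       n_cliques=4, clique_size=5, seed=11)
design, measurements, tables, truth = generate_bundle(cfg)

pc = PipelineConfig(output_dir="results", n_boot=199)
res = run_pipeline(pc, design, measurements, tables)

print(res.vector_groups.round(3))
print(res.topology.round(3))
print(round(res.plspm.gof, 4))
```

prints

```
           vector_length_mean  vector_length_std  vector_angle_deg_mean  vector_angle_deg_std
treatment
Ps.M                    0.977              0.015                 42.602                 0.434
Ps.P                    1.094              0.019                 39.886                 0.496
Up.M                    0.983              0.019                 41.952                 0.602
Up.P                    1.336              0.019                 39.650                 0.269

         node_number  edge_number  average_degree  average_path_length  average_clustering_coefficient  modularity
network
Ps.P             104          128           2.462                4.390                           0.327       0.824
Up.P              84          235           5.595                2.822                           0.378       0.472
Ps.M             108          181           3.352                3.613                           0.432       0.775
Up.M             108          153           2.833                4.045                           0.395       0.801

0.733
```

Every treatment's mean vector angle sits below 45°, i.e. all synthetic
communities are N-limited, with the mixed-stand angles shifted toward the
45° balance point and their vector lengths (C limitation) reduced relative
to the pure stands — the pattern the generator's default means encode. The
topology table gives the six per-network graph metrics, and the final
number is the PLS-PM goodness of fit.

The same pipeline runs from the shell:

```
ecostoichnet simulate --out bundle/
ecostoichnet run --inputs bundle/ --out results/
```

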