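# emnet

Plant–soil microbiome coupling analysis for forest amplicon surveys:
how does the ectomycorrhizal (EM) fungal community of focal trees relate
to the richness of the neighboring plant community, and which abiotic
(soil/litter chemistry) and biotic (rhizosphere bacterial network)
factors mediate that relationship?

The package is aimed at microbial ecologists working with ASV-level count
tables from plot-based forest surveys (e.g. pure vs mixed stands), and at
methodologists who want a fully seeded, testable reference implementation
of the analysis chain such studies use.

## What it computes

- **Alpha diversity** per sample: richness, Shannon *H* = −Σ pᵢ ln pᵢ,
  Gini–Simpson 1 − Σ pᵢ², bias-corrected Chao1, ACE.
- **Beta diversity** (Baselga partition of Sørensen dissimilarity):
  β_sor = (b+c)/(2a+b+c) split into turnover β_sim = min(b,c)/(a+min(b,c))
  and nestedness β_sne = β_sor − β_sim, pairwise and multiple-site.
- **Co-occurrence networks**: signed Spearman graphs (|ρ| ≥ 0.6 with
  calibrated p-thresholds), whole-network topology, per-sample induced
  subnetworks, and the **Multi-net** complexity index (mean of z-scored
  node number, edge number and betweenness across samples).
- **Node roles / keystone taxa**: within-module degree z-score Zi and
  participation coefficient Pi = 1 − Σ_s (k_is/k_i)², classified at
  (2.5, 0.62) into peripherals, connectors, module hubs and network hubs.
- **Forest-type effects**: log response ratio lnR = ln x̄_E − ln x̄_C with
  variance v = SD_E²/(n_E x̄_E²) + SD_C²/(n_C x̄_C²), plus one-way ANOVA
  with Duncan's multiple range letters.
- **Association models**: ln–ln OLS regressions of EM metrics on plant
  richness (overall and per forest type), collinearity screening
  (|r| < 0.6), random-intercept mixed models
  `EM ~ plant + env + plant×env + (1|site)` (REML), and random-forest
  contributions with permutation importance.
- **PLS path modeling** (from first principles): latent blocks
  plant → {abiotic, biotic} → EM diversity, mode A outer estimation, path
  scheme inner weighting, bootstrap CIs, effect decomposition and
  GoF = √(mean communality × mean R²).
- **Synthetic data generator** with known ground truth (coupling slope,
  planted bacterial correlation blocks, site effects), so parameter
  recovery is measurable end to end.

## Worked example

```python
from emnet import (SimParams, simulate_dataset, alpha_diversity,
                   beta_partition, response_ratio_table)
from emnet.network import (filter_by_relative_abundance, build_network,
                           topology, zi_pi)

ds = simulate_dataset(SimParams(seed=1))          # 18 plots, 3 forest types
alpha = alpha_diversity(ds.fungal_table)
print(alpha.head(3).round(3))

rr = response_ratio_table(alpha, ds.metadata["forest_type"], control="PF")
print(rr[rr.metric.isin(["richness", "shannon"])]
      [["metric", "treat", "lnR", "percent_change", "p"]].round(4))

net = build_network(filter_by_relative_abundance(ds.fungal_table, 1e-4),
                    r_cut=0.6, p_cut=0.001)
t = topology(net)
print(f"network: {t['node_num']} nodes, {t['edge_num']} edges")
print(zi_pi(net)["role"].value_counts().to_dict())
```

Output:

```
     richness  shannon  simpson  chao1   ace
PF1        44    3.312    0.955   44.0  44.0
PF2        56    3.671    0.969   56.0  56.0
PF3        29    2.976    0.930   29.0  29.0
  metric treat    lnR  percent_change      p
richness   QPF 0.1792         19.6226 0.0955
richness   QBF 0.3036         35.4717 0.0107
 shannon   QPF 0.0581          5.9868 0.0789
 shannon   QBF 0.0977         10.2656 0.0030
network: 321 nodes, 942 edges
{'peripheral': 319, 'connector': 2}
```

Reading it: EM fungal richness in the broadleaf-mixed plots (QBF) is
35.5% higher than in pure stands (lnR = 0.30, p ≈ 0.01); the all-sample
co-occurrence network has 321 taxa connected by 942 significant
correlations, two of which act as connectors (keystone candidates)
between modules. The multiple-site Sørensen dissimilarity of this dataset
(0.923) is almost entirely turnover (β_sim 0.912 vs β_sne 0.011) —
species replacement, not loss, drives compositional differences.

The same stages are scriptable from the shell:

```bash
emnet simulate --seed 1 --out run/data
emnet diversity --table run/data/fungal_table.tsv --out run/div
emnet run-all --seed 1 --out run/full     # every stage, byte-reproducible
```

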