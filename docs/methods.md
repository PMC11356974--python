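# Methods

`emnet` implements an analysis chain for linking the ectomycorrhizal (EM)
fungal community of focal forest trees to the richness of their neighboring
plant community: alpha diversity, Sørensen beta-diversity partitioning,
signed Spearman co-occurrence networks with per-sample subnetwork
complexity, Guimerà–Amaral node roles, log response ratios across forest
types, interaction mixed models, random-forest contributions, and a partial
least-squares path model. A synthetic-data generator with known ground
truth drives the pipeline so every stage is testable.

## Synthetic study design

The generator emulates a three-forest-type survey — pure oak (PF), oak–pine
(QPF) and oak–broadleaf (QBF) stands — with six plots per type and one
composite sample per plot (n = 18). Each plot carries a plant richness
value, eight soil/litter covariates, an EM fungal count table and a
rhizosphere bacterial count table.

Generating model, per sample:

- **Plant richness** ~ Poisson around the forest-type mean (defaults
  PF 12, QPF 20, QBF 24 species per plot; mixed stands richer than pure,
  as is typical for temperate secondary forests), truncated at ≥ 1.
- **Covariates** (SOC, TN, LC, LP in g kg⁻¹; pH; NH₄⁺, NO₃⁻, SAP in
  mg kg⁻¹) are Gaussian around field-plausible means, sharing a latent
  factor with log richness (loading `env_richness_cor`, default 0.5) so
  covariate–richness collinearity is present without a causal DAG.
- **EM community**: the log of the realized taxon pool is
  `base_log_pool + coupling_beta · ln(richness) + Σ env_effect_j z_j +
  site + ε`, with a Gaussian site intercept (`site_sd` 0.1) and residual
  noise (`noise_sd` 0.1). The realized taxa are a uniform draw from a
  400-taxon pool, relative abundances are symmetric Dirichlet
  (concentration 1), and counts are multinomial at a fixed sequencing
  depth of 10⁴ reads (Dirichlet–multinomial compositional noise; depth and
  rarefaction conventions are unreported for such surveys, so the depth is
  a package choice recorded in `truth.json`). `coupling_beta` defaults to
  0.5; with `coupling_beta = 0` *and* the default all-zero `env_effect`
  the model is exactly null — richness carries no information about the
  EM community.
- **Bacteria**: 300 taxa, of which planted blocks (default sizes 8 and 6)
  receive an equicorrelated Gaussian copula (within-block latent
  correlation 0.85); all other taxa are independent. Latents map through a
  lognormal abundance profile to multinomial counts. Keeping the planted
  blocks a small fraction of the pool matters: with a small total pool the
  multinomial denominator couples the blocks (compositional closure) and
  produces spurious cross-block correlation. The per-sample number of
  bacterial taxa grows weakly with richness (`bacteria_richness_coupling`
  0.3) so cross-kingdom network structure covaries with the plant signal.

Not emulated: phylogenetic signal, spatial autocorrelation, realistic
ITS/16S read error, taxon-specific habitat preferences. Passing tests
therefore demonstrate correctness of the estimators and recoverability of
planted effects under compositional noise — not robustness to every
property of real amplicon data.

## Diversity

Alpha indices per sample: richness (taxa with count > 0), Shannon entropy
in nats, Gini–Simpson `1 − Σp²` (λ and inverse-Simpson variants via
`simpson_variant`), bias-corrected Chao1 `S + F₁(F₁−1)/(2(F₂+1))`
(classic form via flag) and ACE with the standard rare/abundant cutoff at
10 individuals and γ² clamped at 0. Chao1/ACE delegate to scikit-bio;
degenerate communities (no rare taxa, all singletons) fall back to
observed richness. No rarefaction is applied; per-sample depth is the
caller's responsibility.

Beta diversity uses the Baselga partition of pairwise Sørensen
dissimilarity: `β_sor = (b+c)/(2a+b+c)`, turnover
`β_sim = min(b,c)/(a+min(b,c))`, nestedness `β_sne = β_sor − β_sim`, with
the multiple-site analogues aggregating `Σ min` and `Σ max` of the
pairwise unique fractions. The per-plot reduction used in regressions is
the mean pairwise dissimilarity of a plot to all others (an LCBD-style
squared-deviation contribution is available via `summary="lcbd"`); the
reduction used is recorded in the result object.

## Co-occurrence networks

Taxa below a total relative abundance of 10⁻⁴ (0.01%) are removed, then
all pairwise Spearman correlations are thresholded: fungal networks keep
|ρ| ≥ 0.6 at p ≤ 0.001, cross-kingdom (fungi + bacteria concatenated)
networks |ρ| ≥ 0.6 at p ≤ 0.05. The magnitude criterion admits negative
edges; the sign is stored per edge.

**Spearman p-values.** The default (`p_method="auto"`) mirrors R's
`cor.test`: pairs of untied vectors use the permutation null of ρ — exact
enumeration for n ≤ 9, a shared fixed-seed Monte-Carlo null (2·10⁵ draws)
for n ≤ 50 — while tied pairs and larger n use the t approximation with
tie-corrected ρ. The t approximation alone is measurably anticonservative
in the far tail at n = 18 (≈ 1.4× the nominal rate at p = 0.001), which
distorts edge counts at the stringent fungal threshold; the permutation
null restores calibration (mean spurious edges 0.79 per 40-taxon null
table, 780 pairs). `p_method="t"` forces the classical approximation.
No multiple-testing correction is applied by default, matching common
practice for thresholded co-occurrence networks.

**Topology.** Node/edge counts, positive/negative tally and their ratio
(flagged undefined when no negative edges exist), mean degree, mean
shortest-path length over reachable pairs, density, degree assortativity
(undefined on degree-regular graphs), and mean normalized betweenness,
degree and eigenvector centralities. Eigenvector centrality is computed
on the largest connected component by dense symmetric eigendecomposition —
the ARPACK route starts from a random vector and would break run-to-run
determinism.

**Per-sample subnetworks and Multi-net.** Each sample's subnetwork is the
subgraph induced on the network taxa present (count > 0) in that sample;
node number, edge number and mean betweenness are recorded, and the
Multi-net index is the per-sample mean of the three metrics z-scored
across all 18 samples (pooled across forest types so type comparisons
share a scale; a constant metric contributes 0). The pipeline extracts
subnetworks from the all-sample network by default: with six samples per
type, the fungal edge rule admits only rank-perfect pairs within a type,
so per-type subnetworks are nearly degenerate. Per-type extraction remains
available (`subnetwork_source="per_type"`).

**Node roles.** Modules by greedy modularity maximization on the unsigned
graph (deterministic; Louvain with a seed via `method="louvain"`), then
within-module degree z-score `Zi` (0 for singleton or degree-constant
modules) and participation coefficient `Pi = 1 − Σ_s (k_is/k_i)²`. Roles
use the (2.5, 0.62) grid — peripherals, connectors, module hubs, network
hubs — with boundary values assigned to the lower category. Non-peripheral
nodes are treated as keystone taxa and their relative abundances are
Spearman-correlated with every diversity/topology indicator and plant
richness. Note `Pi` cannot exceed 0.5 in a two-module graph, so connectors
can only arise where at least three modules exist.

## Forest-type effects

Log response ratio per variable and treatment group vs the PF control:
`lnR = ln x̄_E − ln x̄_C`, variance
`v = SD_E²/(n_E x̄_E²) + SD_C²/(n_C x̄_C²)`, percent change
`(e^lnR − 1)·100`, significance by the meta-analytic normal approximation
`lnR/√v` (stars at 0.05/0.01); a one-way ANOVA p across all groups is
reported alongside since group effects are also assessed that way.
Variables spanning zero (z-scored indices such as Multi-net) have no
defined ratio of means and are reported as NaN rather than an error.
Group comparisons additionally use one-way ANOVA with Duncan's multiple
range letters (protection level α, studentized range at
`α_p = 1−(1−α)^(p−1)`, harmonic-mean group size for unequal n).

## Association models

Diversity–richness regressions are OLS of ln(metric) on ln(plant
richness), overall and within each forest type; metrics spanning zero stay
on the raw scale (signed shifted-log available), with the transform
recorded per row. Covariates are screened by greedy collinearity pruning:
repeatedly drop, from the most correlated violating pair (|r| ≥ 0.6), the
member with the larger mean absolute correlation to the remaining set.

Environmental moderation uses the random-intercept model
`EM ~ plant + env + plant:env + (1|site)` fitted by REML (statsmodels
MixedLM; ML fallback, then Powell, on optimizer failure), with Wald tests
for fixed effects. The covariate is z-scored by default so intercept and
interaction terms are comparable across covariates; the focal predictor
stays on the ln-richness scale so its slope is directly interpretable.
A variance estimate at the zero boundary (≤ 1e-8) is flagged `singular`,
where the fit provably coincides with OLS.

Random-forest contributions: regression forest (500 trees,
mtry = ⌈p/3⌉), permutation importance (drop in R², 10 repeats),
out-of-bag R² as explained variance, and model significance by permuting
the response (999 permutations by default; the bundled pipeline and test
suite use 9–99 permutations and 50–200 trees — at n = 18 the importance
ranking stabilizes well below the defaults, and the smaller sizes keep a
full run in tens of seconds). The spec-level question of what "the
plant–EM relationship" means as an RF target is resolved conservatively:
the EM metric itself is the response with plant richness included among
the predictors, and the choice is recorded in the output.

## PLS path modeling

Implemented from first principles (Lohmöller alternating algorithm):
standardized indicators, mode A (reflective) outer estimation, path
weighting scheme for the inner approximation (centroid/factorial
available), iterated until the maximum outer-weight change < 1e-7 (cap
300; per-iteration sign stabilization prevents oscillation between
equivalent orientations). After convergence each latent is oriented so
its largest-magnitude loading is positive — the same convention used for
ordination axes. Inner path coefficients are OLS of each endogenous
latent on its predecessors; R² per endogenous block; communality = squared
loading; GoF = √(mean communality × mean R²). Effects decompose along
directed routes (the path matrix is nilpotent for acyclic models), with
total = direct + indirect verified structurally. Bootstrap (500 seeded
resamples) yields percentile CIs and two-sided sign-based p per path;
degenerate resamples (constant indicator) are skipped and counted.

The study-shaped specification uses four blocks — plant (richness),
abiotic (SOC, TN, LC, LP), biotic (Assort, Avgdist, Ceneig from the
cross-kingdom network), EM diversity (five alpha indices, the first two
PCoA axes of the Bray–Curtis dissimilarity, and the subnetwork topology
set including Multi-net) — with paths plant→{abiotic, biotic, EM} and
{abiotic, biotic}→EM. The EM block deliberately mixes alpha, beta and
topology indicators in one reflective block, mirroring the study design
it reproduces; its heterogeneity (indicators need not be mutually
consistent reflections of one construct) is a known caveat. PCoA on
Bray–Curtis is the default beta-ordination (plain PCA available), with
axis signs fixed by the largest-magnitude-score convention.

Mode A attenuates path coefficients when indicators are noisy (the latent
is estimated, not observed); recovery tests therefore plant paths on
unit-variance latents and use either single indicators or low measurement
noise, where the planted standardized coefficients are the correct
expectation.

## Determinism and problem sizes

Every stochastic step (simulation, module detection when Louvain is used,
bootstrap, random forest, response permutations) derives from the run
seed; the Monte-Carlo Spearman null uses an internal fixed seed, as a
critical-value table. Two `run-all` invocations with the same seed write
byte-identical artifacts (verified file-by-file in the test suite).

Monte-Carlo sizes used by the test suite and acceptance script: 100 null
tables (40 taxa × 18 samples) for edge calibration; 1000 replicates for
OLS/ANOVA type-I error; 200 replicate studies for coupling-slope and PLS
path recovery; 20 replicate designs for the mixed-model interaction and
planted-module ARI; 50 fixtures for connector classification; 10⁴
replicates for lnR bias. These sizes give Monte-Carlo standard errors
comfortably below the assertion tolerances.

## Limitations

- Spearman co-occurrence on relative counts is not compositionality-aware
  (no SparCC/SPIEC-EASI); closure-induced correlation is mitigated only by
  the large taxon pool.
- The per-plot beta reduction and the RF target are package choices where
  the underlying field conventions are ambiguous; both are labeled in
  outputs.
- PLS-PM blocks are reflective by default; formative (mode B) estimation
  is available but untested against planted truth.
- The mixed model supports a single random intercept (site); crossed or
  nested designs are out of scope.
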