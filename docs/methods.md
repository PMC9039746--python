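# Methods

This note documents the models, numerical choices and known limitations
behind each `salinet` module, in the order data flows through the
pipeline.

## Data model and cleaning rules

An analysis operates on four aligned objects: an integer OTU count
table (samples × OTUs), a taxonomy (six ranks kingdom→genus plus a
functional group in {algae, protozoa, fungi, unassigned}), per-sample
metadata, and a rooted phylogeny whose tips are OTU ids. Cleaning
removes OTUs present (count > 0) in fewer than two samples — presence,
not relative abundance, is the criterion — and OTUs whose lineage
contains "metazoa" or "streptophyta" as a case-insensitive substring at
any rank, because reference releases place those labels at varying
ranks. Table orientation on disk is declared by a flag (default
OTUs-as-rows, the common amplicon convention); it is never
auto-detected, since silent transposition is the worst failure mode a
parser can have.

Salinity classes partition [0, ∞): salt ≥ 8.75‰, brackish ≥ 3.535‰,
freshwater below. Boundary values go to the higher class, matching the
closed lower bounds as printed. Composition percentages use the table's
total OTU count as the richness denominator (OTUs with an unassigned
functional group stay in the denominator) and an explicit total
sequence count as the abundance denominator, both rounded to two
decimals.

## Synthetic community generator

The generator exists so that every downstream statistic can be tested
against known ground truth. It emulates a 41-sample lake survey
spanning <1‰ to ~11.3‰ salinity in three classes (≈10 salt samples
near 11.3‰, ≈10 brackish near 6.2‰, the rest freshwater below 1‰),
with a few-hundred-OTU pool.

* **Phylogeny** — a Yule (pure-birth) tree, branch lengths rescaled to
  unit mean root-to-tip depth. All tips are contemporaneous in
  expectation; no rate heterogeneity.
* **Niche traits** — per-OTU salinity optima evolve by Brownian motion
  (default rate 9‰² per unit depth, root at 4‰), so optima are
  phylogenetically conserved — the signal βNTI requires — and span
  roughly the observed gradient.
* **Communities** — in a sample at salinity *x*, OTU *i* receives
  weight `A_i · exp(−s(x−μ_i)²/(2σ²))` (lognormal metacommunity
  abundance `A_i`, σ(log) = 1.5; niche breadth σ = 2‰), mixed with the
  raw metacommunity at dispersal rate *m*, then counts are one
  multinomial draw per sample at the configured depth. `s = 0` or
  `m = 1` is exactly neutral sampling from one shared pool.
* **Regimes** — the packaged fixtures use `selection` (s = 2,
  m = 0.05) and `neutral` (s = 0, m = 1) at depth 5,000 reads. The
  depth keeps the reads-per-OTU ratio of a ~25,000-read, ~2,500-OTU
  survey when the pool is scaled to 300 OTUs; this preserves realistic
  presence turnover between samples, which matters because shared taxa
  contribute zero to nearest-taxon distances and a saturated table
  would mute every phylogenetic turnover signal.
* **Taxonomy** — OTUs are assigned round-robin to the three functional
  groups and to twelve synthetic orders so order-level summaries
  (degree proportions, biomarker features) are exercised.

What the generator does **not** emulate: sequencing error and chimeras,
PCR amplification bias, overdispersion beyond multinomial sampling,
spatial autocorrelation of the environment, and multi-modal or skewed
niche responses. Passing tests demonstrate correct statistical
machinery and qualitative parameter recovery, not that real lake data
meet these assumptions.

## Diversity and ordination

Shannon diversity uses natural logarithms (so H′ ≤ ln S). Bray–Curtis
is Σ|x−y|/Σ(x+y) on raw counts; it is a semi-metric (triangle
inequality violations are expected and permitted). Geographic distances
are haversine great circles with Earth radius 6371.0088 km.

NMDS minimises Kruskal stress-1 by iterative isotonic regression with
SMACOF updates, best of `n_starts` (default 50) seeded random starts,
convergence at stress change < 1e-9, coordinates centred.

PERMANOVA partitions squared distances into among/within-group sums
(pseudo-F), permuting group labels; p = (1 + #{F* ≥ F}) / (1 + n_perm),
so p > 0 always. Ties count as exceedances; consequently the smallest
achievable p for small balanced designs is the probability of the
label-permutation orbit, not 1/(n_perm+1). The Mantel statistic is the
Pearson correlation of lower triangles (Spearman optional); the partial
variant correlates residuals of both triangles on the conditioning
triangle, permuting the rows/columns of the first matrix and
re-residualising each repetition. When conditioning explains a triangle
completely, the residual correlation is defined as 0 rather than the
sign of numerical noise.

CCA follows the classical correspondence formulation: with P the
grand-total-normalised table, r and c its margins, the standardised
residual matrix is Q = (P − rcᵀ)/√(rcᵀ); total inertia is ‖Q‖²_F and
constrained inertia is the squared norm of the projection of Q onto the
row-weighted, centred constraint space (verified against an independent
implementation to 1e-7, including the partial/conditioned variant).
Per-variable "explained variance" is **marginal**: the inertia fraction
of a single-constraint CCA — the alternative (forward-sequential
contributions) would depend on an ordering the analysis does not
define. Each variable's pseudo-F is CI/((TI−CI)/(n−2)), tested by 999
permutations of its sample rows. VIFs are 1/(1−R²) from regressing
each variable on the rest; selection iteratively drops the largest
until all are below 10. Variation partitioning solves the
inclusion–exclusion system over all unions of predictor sets (2 or 3
sets), so unique + shared + unexplained sums to 1 exactly; negative
shared fractions are reported as computed, as is conventional.

The multivariate regression tree predicts the row-normalised community
matrix from environmental thresholds. Growth is best-first on
sum-of-squares gain with candidate splits at midpoints of sorted unique
values (min leaf 2, max 8 leaves), which makes the size-s tree nested
in the size-(s+1) tree; tree size is then chosen by repeated k-fold
cross-validation (default 10-fold) over sizes, either at the minimum
mean CV relative error (default) or by the one-standard-error rule
(flag). The repeated-CV default is 1000 repetitions; the pipeline and
tests run fewer (50–100), which is ample at tens of samples.

## Indicator species

IndVal for OTU i in group g is √(A·B): specificity A = group mean
abundance / summed group means, fidelity B = occurrence fraction within
the group. The statistic is the maximum over groups; significance is by
group-label permutation. Both √(A·B) and A·B are reported, since
published thresholds do not always state the scale; the 0.6 cut is
applied to √(A·B). The indicator flag uses p ≤ p_max: at 999
permutations the smallest attainable p is exactly 1/1000, so a strict
"< 0.001" could never be satisfied. No group-size correction is applied
(equalised group weights are a documented non-default in the field).

## Co-occurrence networks

OTUs present in ≥25% of samples enter all-pairs Spearman correlation
(average ranks for ties, t-approximation p-values; constant vectors are
excluded with a warning). Benjamini–Hochberg adjustment runs over all
tested pairs within one network; edges need |ρ| > 0.6 and q < 0.05.
The environment–OTU network reuses the machinery with environmental
variables as typed nodes; the OTU–OTU and OTU–environment families are
BH-adjusted separately (pooling them is the alternative; the choice is
isolated in one place).

Topology: avgK = 2L/N and connectance = 2L/(N(N−1)) are closed forms;
mean path distance averages over reachable pairs only and the diameter
is taken on the largest component, keeping metrics finite on
disconnected graphs; average clustering assigns 0 to nodes of degree
< 2; degree centralisation is Freeman's Σ(k_max−k_i)/((N−1)(N−2)) and
betweenness centralisation Σ(b_max−b_i)/(N−1) on normalised
betweenness; the power-law R² is the coefficient of determination of
the least-squares line through log(frequency) vs log(degree) over
degrees with nonzero frequency (no binning; CCDF-based fits would be an
alternative surface). Modularity uses greedy (CNM) maximisation, which
is deterministic given the graph; published modularity values from
interactive tools depend on unstated algorithms and resolutions, so Q
is compared only against the package's own nulls, never across tools.
The null ensemble draws G(N, L) graphs — exactly N nodes and L
uniformly placed edges — and reports means, SDs and z-scores of the
observed clustering, path distance and modularity (default 10,000
graphs; metric subset selectable because modularity dominates runtime
on large graphs).

## Assembly null models

βMNTD(k,m) = ½[Σ_i f_ik·min_{j∈m} d_ij + Σ_j f_jm·min_{i∈k} d_ij] with
f relative abundances (abundance-weighted, the default) or equal
presence weights, and d the patristic distance. A taxon present in both
samples contributes zero. The implementation is vectorised by
precomputing, per sample, each OTU's nearest-taxon distance into that
sample. The unweighted mode weights each community equally
(½(mean_k + mean_m)); implementations that average over the pooled
taxon list differ slightly when richness differs.

βNTI shuffles taxon identities uniformly among the tips present in the
analysed table (equivalently permutes the distance matrix), recomputing
βMNTD per repetition (default 999 nulls; tests and the bundled pipeline
use 199, which changes βNTI by O(5%) noise and no classifications near
the thresholds in practice). Pairs with null SD = 0 (e.g. a star
phylogeny) are flagged undefined and excluded from fractions with their
count reported.

RC_Bray draws null communities that preserve each sample's observed
richness and total count: taxa enter with probability proportional to
metacommunity occurrence frequency (without replacement), each gets one
individual, and the remainder is multinomial on metacommunity relative
abundances. RC = 2·[(#{BC_null < BC_obs} + ½·#{BC_null = BC_obs})/n] − 1.
Null draws are generated per sample and paired per repetition — the
marginal null distribution per pair is identical to drawing per pair,
at a fraction of the cost. The metacommunity is the pooled analysis
scope (all samples when run pooled, the class when run per class).

Classification uses strict inequalities exactly as the thresholds are
printed: βNTI > 2 variable (heterogeneous) selection, βNTI < −2
homogeneous selection, else RC < −0.95 homogenizing dispersal,
RC > 0.95 dispersal limitation, else undominated; the boundary values
±2 and ±0.95 therefore fall to the stochastic/undominated side.
Process fractions are computed within salinity classes (and pooled),
with per-class βNTI mean ± SD and a Kruskal–Wallis test across classes.

## Biomarker forests

Order-level relative abundances (unclassified OTUs dropped with a
report) are regressed on salinity with a bagged regression forest
(sklearn's RandomForestRegressor behind a pluggable-learner seam;
default 1000 trees). Recursive feature elimination halves the feature
count per step ranked by impurity importance, re-ranked within each CV
fold; the CV error per subset size is the MSE averaged over folds and
repeats (default 10-fold × 5 repeats), and the selected size is the
argmin. "Predictive accuracy" is reported as out-of-bag variance
explained, 100·(1 − MSE_oob/var(y)) — an interpretation, since
published accuracy percentages for regression forests rarely define
their metric — and is deliberately not clipped below zero. A Wilcoxon
signed-rank test compares actual salinities with out-of-fold
predictions of the selected feature set.

## Pipeline and reproducibility

Stage seeds derive from `crc32(f"{master_seed}:{stage}") mod 2³¹`, so a
single knob reproduces every stage independently. Each run writes a
manifest with parameters, derived seeds and SHA-256 checksums of all
outputs; reruns are byte-identical, and inputs are never mutated. A
failing optional stage (e.g. biomarkers on too few samples) is logged
and recorded in the manifest without aborting the run; the assembly
stage fails in isolation if the tree does not cover the table.

`scripts/acceptance.py` re-derives the headline quantities at
41 samples × 300 OTUs with 999 permutations, 199 assembly nulls and a
500-graph ER ensemble (2000 graphs for the density sanity check) —
sizes at which every reported statistic is stable to well under its
seed-to-seed variability.

## Known limitations

* Spearman-correlation networks capture association, not interaction;
  no conditional-dependence correction is attempted.
* The RC_Bray metacommunity is the analysed sample pool; small pools
  bias occurrence frequencies toward the samples being tested.
* The MRT explores axis-aligned single-variable splits only.
* CCA assumes unimodal (chi-square distance) responses; strongly linear
  gradients are better served by RDA, which is out of scope.
* The generator's Gaussian niche with a single global breadth cannot
  express asymmetric salt tolerance (euryhaline vs stenohaline taxa).
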