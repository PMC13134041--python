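# Methods

This note documents the statistical procedures the package implements, the
defaults and why, the synthetic generator's model and its limits, and the
numerical conventions that matter for reproducing results.

## Feature filtering

Amplicon feature tables arrive as non-negative integer count matrices
(samples × ASVs).  Filtering removes, in one pass: features with no
assignment at a required rank (default **class**); features whose total
count across all samples falls below a minimum (default **2 reads** — a
singleton-read ASV is indistinguishable from error); and features whose
lineage contains, case-insensitively, any term from a deny-list (default
chloroplast, mitochondria, Viridiplantae, Metazoa).  In 16S mode, features
classified to domain Eukaryota are also removed, since a prokaryotic
primer set should not yield them; for ITS data domain-level screening is
left off by default because fungal references legitimately sit inside
Eukaryota.  Lineages are parsed by splitting on `;` and stripping `x__`
prefixes, covering both SILVA- and UNITE-style strings.  Samples emptied
by filtering are kept and logged: dropping shallow samples is a
rarefaction-depth decision and the two concerns are deliberately
orthogonal.  Filtering is idempotent.

## Bootstrapped rarefaction and diversity

Sequencing depth varies by orders of magnitude between samples, so all
diversity estimates are computed on even subsamples.  Two modes:

- **without replacement** (classical rarefaction,
  multivariate-hypergeometric): samples below the target depth are dropped;
- **with replacement** (the bootstrap mode, multinomial at the sample's
  observed proportions): any sample with ≥ 1 read is retained.

The pipeline's defaults are a depth of **500 reads** and **10 bootstraps**
— appropriate for low-biomass, low-diversity surface communities such as
grape-berry epiphytes, where deeper thresholds would discard many samples.
Alpha diversity (observed features; Shannon entropy) is the element-wise
**median** of the bootstrap values.  Beta diversity (Jaccard on
presence/absence, Bray–Curtis on counts) is summarised by the **medoid**:
the bootstrap distance matrix minimising the summed Frobenius distance to
the other bootstraps, with ties broken to the lowest bootstrap index.  The
medoid — unlike an element-wise mean — is always a realisable distance
matrix produced by an actual rarefaction.

Shannon entropy is reported in **bits** (log base 2) everywhere; every
documented value and test constant uses that convention.  A pair of
all-zero samples is assigned distance 0 (logged loudly) so permutation
tests downstream never see NaN.

## k-mer decomposition

As a lightweight alternative to phylogenetic metrics, ASV counts can be
re-expressed in k-mer space: the count of k-mer *m* in sample *s* is
Σ_f count(s, f) · occurrences(m, seq(f)).  Sequence-similar ASVs then share
features, so k-mer beta diversity blends abundance shifts with sequence
divergence.  Default k = 16; k-mers containing N are skipped; reverse
complements are not collapsed (amplicons are orientation-fixed).  For
equal-length N-free sequences the transformation conserves read mass up to
the factor (L − k + 1).

## Ordination

PCoA is classical metric MDS: double-centre −½D², eigendecompose, scale
eigenvectors by √λ for positive eigenvalues.  Negative eigenvalues (from
non-Euclidean dissimilarities such as Bray–Curtis) are reported but
contribute no coordinates; proportion explained is normalised by the sum
of positive eigenvalues only.

## Distance decay and the Mantel test

Geodesic distances are haversine great-circle distances (mean Earth radius
6 371 008.8 m); at vineyard-to-regional scales the error against
ellipsoidal geodesics is far below the sampling noise.  The Mantel
statistic is the Spearman correlation (average ranks on ties) between the
upper triangles of the community and geographic distance matrices.
Significance permutes the sample labels of the second matrix
(simultaneous row/column shuffles); ranks are permutation-invariant, so
the implementation ranks once and gathers, making 999 permutations cheap.
The test is two-sided on |ρ| with the add-one estimator
p = (1 + hits)/(1 + N), so p is never 0; an exact mode enumerates all n!
permutations and is verified against a brute-force oracle in the tests.

The distance-decay report adds an OLS regression of community on
geographic distance over sample pairs with a 95% CI on the slope.  Pairs
are not independent, so this regression is **descriptive only**; inference
comes from the Mantel test.  The report says so.

## PERMANOVA family

For a distance matrix and a grouping with a groups:
SS_total = Σ_{i<j} d²_ij / n, SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g,
SS_among = SS_total − SS_within,
pseudo-F = (SS_among/(a−1)) / (SS_within/(n−a)), and the reported effect
size is **R² = SS_among/SS_total**.  p-values come from label permutation
with the add-one estimator; an exact mode enumerates the distinct
assignments of the label multiset.  On Euclidean distances of univariate
data the pseudo-F equals the classical one-way ANOVA F — the test suite
checks this identity to 1e-9 as a cross-validation between the two code
paths.

Pairwise PERMANOVA runs every group pair, BH-adjusts the p-values, and
builds a compact letter display by insert-and-absorb: two groups share a
letter exactly when their adjusted p exceeds α (default 0.05).

The **stratified** variant tests a factor (cultivar) while controlling a
confounder (site): factor labels are permuted only within each stratum,
and the statistic pools per-stratum sums of squares with pooled degrees of
freedom Σ(a_s − 1) and Σ(n_s − a_s).  Any between-site structure is held
fixed under the null, making this the permutation analogue of "testing
cultivar after factoring for site".  A factor constant within every
stratum is unresolvable confounding and raises an error.  Alternative
two-way designs (sequential partitioning of a joint model) exist; the
restricted-permutation reading was chosen because it makes the fewest
modeling assumptions and calibrates exactly by construction — the tests
verify type-I error at α = 0.05 within binomial bounds under null
simulations for all three PERMANOVA forms and the Mantel test.

ANOVA on alpha diversity: one-way classical F, or two-way main effects
with **type II** sums of squares and no interaction — vineyard × cultivar
designs are unbalanced by construction, and type II keeps main-effect
tests interpretable there.  Spearman trend tests (e.g. alpha diversity vs
row position) use exact permutation p for n ≤ 9 and the t-approximation
beyond.

## Gamma diversity and accumulation

Gamma diversity of a sample set is the alpha metric computed on the
**pooled** count vector — for Shannon this is the entropy of the pooled
community, not the mean of per-sample entropies, matching the reading of
gamma as cumulative diversity of the landscape unit.  Accumulation curves
draw x samples per site (with replacement by default; without is an
option), pool, and compute the metric, over n_iter iterations (default
10); bands are t-based 95% CIs (mean ± t₀.₉₇₅,ₙ₋₁·sd/√n).  With 10
iterations the bands are wide — that is stated rather than hidden; raise
n_iter for tighter bands.  Per-draw richness can never exceed the pooled
richness of the site (a subset-union bound the tests check exactly), and
with-replacement means converge to that asymptote as x grows.

## Kriging

Diversity surfaces are interpolated by Gaussian-process regression with
kernel  σ² · Matérn(ℓ, ν) + white noise, on coordinates projected to local
planar meters (equirectangular about the centroid — at plot extents ≪
Earth radius the projection error is negligible).  Values are standardized
before fitting and de-standardized on prediction.  Defaults: ν = 1.5
(configurable 0.5/1.5/2.5), 10 random log-uniform restarts plus one
heuristic start at the median inter-point distance, length-scale bounds
[0.1 × min, 10 × max inter-point distance], noise variance ∈ [1e-8, 10] on
the standardized scale.  The optimizer trace (per-start hyperparameters
and log marginal likelihoods) is retained on the fitted model.  Pinning
the noise bounds near zero turns the GP into an exact interpolator; the
tests verify sub-1e-6 error at training points in that regime, and
factor-of-2 recovery of a known 30 m length scale on 100-point grids.
Identifiability warning: when the true correlation length approaches the
plot extent, the length scale is only weakly identified and estimates
scatter widely — recovery claims in the tests use grids whose extent is
3× the true scale.

## Taxon-coordinate screening

An exploratory screen for taxa with spatial gradients (e.g. a
phytopathogen encroaching from a field edge): per-sample relative
abundances of every taxon above a prevalence threshold (default 10%) are
Spearman-correlated with latitude and longitude.  BH correction across
all tests in the screen is the default; `correction="none"` reproduces
the uncorrected exploratory behaviour.  Rank correlations saturate when a
taxon is absent from many samples (tied zeros), so low-prevalence taxa
have bounded attainable |ρ| — another reason for the prevalence filter.

## The synthetic vineyard generator

The generator exists so every stage above can be validated against known
truth.  It emulates: a regular grid of vines per site (default 7 × 7
sampled vines at 10 m × 8 m, i.e. a sampling grid over a larger planting),
two sites 1.5 km apart, interplanted cultivars (60/25/15%), and
multinomial reads at depth 2000 per sample (negative-binomial total depth
optional).

Log-propensities for core taxon t at vine v:

    η(t, v) = intercept_t + site(t, s(v)) + cultivar(t, c(v))
              + w_t · GRF_t(v) + ε(t, v)

with intercepts N(0, 1) (community unevenness), site effects N(0, 2),
cultivar effects N(0, 0.5), per-taxon independent Gaussian random fields
with exponential covariance (variance 1.5², length scale 20 m), log-normal
loadings w_t (log-sd 0.5), and noise N(0, 0.5).  Relative abundances are
the softmax over taxa within a vine — effects are compositional, as
sequencing is.  Rare taxa (default 20) are present only within 10 m of a
random focal vine; one edge-gradient taxon has η linear in a coordinate
axis (0.18 log-units/m about the site centroid, intercept 0.5), strong
enough that it carries the largest coordinate correlation among all taxa
in the large majority of realisations — the regime the screen is meant to
flag.  Optional contaminant taxa carry organelle/host lineages for
exercising the filter.

Deliberate choices: generation uses **exponential** covariance (Matérn
ν = 0.5) while kriging fits ν = 1.5 — mild misspecification keeps recovery
tests honest.  Site-effect sd (2.0) dominates cultivar sd (0.5) so the
generator reproduces, at the level where it is literally assertable, the
qualitative finding that site separates communities more strongly than
cultivar.  All randomness flows from a single seed; identical seeds give
bit-identical datasets.

What the generator does **not** emulate: mechanistic dispersal (wind,
vectors), temporal dynamics, read-level sequence error, chimeras, or taxon
co-occurrence interactions.  Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated
generative assumptions — not that real vineyard data satisfy those
assumptions.

## Numerical conventions

- Permutation p-values use (1 + hits)/(1 + N); exact modes divide by the
  full enumeration count with the identity included.
- Statistic comparisons in permutation tails use a 1e-12 slack so ties at
  the observed value count as hits on every platform.
- Distance matrices are validated symmetric within 1e-12 with a zero
  diagonal (enforced by the scikit-bio container).
- Medoid ties break to the lowest bootstrap index; compact-letter columns
  are ordered by first group membership; both make outputs deterministic.
- Every stochastic function takes an explicit seed; the CLI defaults to
  seed 42 and prints it.

## Problem sizes

Default analyses run at the scale the package targets: ~50–100 samples,
hundreds of features, 999 permutations.  Simulation-based checks in the
test suite use 10–50 replicates with 19–199 permutations and the null
calibrations use 300 replicates — sizes chosen to bound Monte-Carlo error
well below the tested margins while keeping the suite quick on a laptop.
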