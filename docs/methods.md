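# Methods

## Study model

The package targets a three-group plot design: a pre-installation
baseline (Y0), plots one year after solar-facility installation (Y1) and
plots six years after (Y6), six plots per group by default, with 23
ecosystem functions in six categories (primary production 2, soil
nutrient pool 5, C cycling 6, N cycling 5, P cycling 3, redox 2).  The
"installation period" contrast is Y1 vs Y0 over one year; the "running
period" contrast is Y6 vs Y1 over five years; both are reported as
per-year relative changes of the group means, so a construction pulse
and a slow operational drift are on the same scale.  Effect intervals
use a percentile bootstrap (2000 resamples, plots resampled within each
year independently); plots cannot be paired across years because soil
sampling is destructive.

## Multifunctionality indices

avgFunc uses min–max scaling per function rather than z-scores, keeping
scores in [0, 1]; a constant function column carries no contrast and is
mapped to 0.5 with a warning instead of failing, so degenerate synthetic
cases survive.  All function directions default to +1 (no inverted
functions are assumed); the direction map is exposed for reuse.  The
multithreshold index needs a per-function reference maximum; with 18
plots the single observed maximum is fragile, so the default is the mean
of the top-2 direction-adjusted values (configurable).  MF-t% is
reported as a *count* of functions, not a proportion — the two differ
only by the constant m and the per-year relative effect is identical
either way.  Boundary semantics are kept exact: a function whose
reference maximum is 0 is met by every plot (0 ≥ 0).

## Synthetic studies and what they do (not) emulate

Functions: per plot, a category-shared latent factor plus independent
noise gives within-category correlation ρ = 0.5 on the z-scale; group
mean shifts default to Y0 = 0, Y1 = +1.0 SD, Y6 = +1.25 SD so the
per-year installation effect dominates the running effect, matching the
qualitative field pattern the indices are meant to expose.  Raw values
are an arbitrary positive affine rescaling per function (absorbed by
standardization).  Environmental covariates are group-coupled (soil
water content rises with facility age, temperature and evaporation
fall); texture fractions are Dirichlet and sum to 100 exactly.

Communities: log-normal(0, σ = 2) base abundances give the heavy tail
the rare/abundant screens need; taxa sit in 8 contiguous latent modules
whose per-sample Gaussian factor (loading 0.7) induces detectable
co-occurrence at 18 samples; reads are multinomial at 50 000 per sample
(plants: Poisson quadrat counts capped at 40).  One dominant (> 0.1 %)
and one ultra-rare (< 0.01 %) taxon are pinned at the probability level
so both abundance classes are always populated.  Planted indicators
(20 per microbial domain, assigned round-robin to groups) receive a ×8
multiplicative enrichment in their group.  Because the data are
compositional, strong enrichment of planted taxa mechanically depresses
the relative abundance of everything else in that group; occasional
"false" indicator calls on non-planted taxa are therefore genuine
compositional shifts, not test failures — the recovery criterion is
evaluated on the fungal domain where the planted share is moderate.

Latent drivers: a small linear-Gaussian system Env → {MA, Div,
Indicator} (paths 0.3) feeds every function with loadings MA = 0.6,
Indicator = 0.6, Div = 0.1, Env = 0.1 (times a function loading of 0.8).
The modest Env paths are a deliberate design choice: they keep "MA and
Indicator are the true drivers" unambiguous in population terms
(population LMG shares ≈ 0.36/0.36 vs 0.10/0.02); a strong upstream
environmental confounder would legitimately absorb LMG credit and the
ranking claim would not be identifiable.  The raw activity table is
generated from MA with conventional magnitudes (MBC ≈ 300 µg C g⁻¹,
SOC ≈ 10 g C kg⁻¹, qCO₂ falling as MA rises).  The planted
compositional indicators and the latent Indicator driver are generated
independently; recovery scoring of observed *composites* against latent
drivers is therefore approximate by construction, and the SEM demo on a
full synthetic study illustrates the machinery rather than a planted
path structure.  Sequencing depth is not reported for the motivating
study; 50 000 reads/sample is a typical MiSeq depth and makes the
4-count filter non-trivial.  All randomness flows from one seed through
a single `numpy` Generator.

## Screens

The ASV filter keeps taxa with ≥ `min_count` (4) reads in at least
⌈prevalence · n⌉ samples.  The literal alternative reading ("≥ 4 in
every sample") is implemented as `mode="strict"` but discards nearly
everything on sparse tables, so the prevalence reading is the default.
IndVal runs on per-sample relative abundances (removing depth
artifacts); permutation p-values use the add-one estimator
(1 + b)/(1 + B), which is never 0, and are BH-adjusted across taxa; the
screen's "significant indicator" is BH q ≤ 0.05.  With count ties the
permutation test is conservative (ties count as ≥), so null calibration
is checked one-sided against the binomial upper bound; the exact
uniformity check uses continuous abundances.  Networks use Spearman on
relative abundances with |ρ| ≥ 0.6 and BH p ≤ 0.05 — common microbiome
practice, config-exposed, since no construction is canonical.  Modules
come from deterministic greedy (CNM) modularity with sorted node order
(no stochastic Louvain), isolated nodes as singletons.  Zi uses the
population SD of within-module degree with the SD = 0 → Zi = 0
convention; Pi = 1 − Σ (k_is/k_i)² with Pi = 0 for isolated nodes.  The
keystone rule defaults to the permissive "or" reading of Zi > 2.5 /
Pi > 0.62, with an "and" flag.

## Diversity

Faith's PD includes the root path (classic definition; flag to exclude).
No rarefaction is applied before diversity — depth is left as a
covariate rather than inventing a normalization.  Gower distances
re-weight over observed traits for pairs with missing values and exclude
zero-range traits with a warning.  FDis embeds species by classical PCoA
with negative-eigenvalue truncation (the dominant convention and the
easiest to verify), then takes the abundance-weighted mean distance to
the abundance-weighted centroid; ≤ 1 present species gives 0.  Guild
richness counts distinct guilds among present taxa whose assignment
confidence is "Highly Probable"/"Probable" (configurable); guild and
pathway maps are supplied (synthetically or by the user), functional
*prediction* being out of scope.

## Attribution

Variance partitioning fits all non-empty union OLS models over the four
factor groups and decomposes the full-model Ezekiel-adjusted R² by
Möbius inversion; components can be slightly negative and are reported
as-is (the identity Σ components = adjR²(full) holds exactly).  LMG
enumerates all orderings exactly up to 8 predictors (via 2^p subset R²s)
and errors beyond that, pointing to the seeded ordering-sampling mode.
Partial correlations use the residual method (identical to the
precision-matrix route) with t-based p on n − k − 2 df.  Mantel permutes
rows and columns of the second matrix jointly, Spearman by default,
one-sided p with the add-one estimator.  Random-forest importance is the
mean out-of-bag MSE increase under feature permutation over a bagged
ensemble of regression trees (max_features = p/3); significance refits
the forest on y-permuted data.  At 18 plots the driver groups enter as
composites (activity PC1; diversity PC1–2; per-domain indicator PC1;
environment PC1–2), keeping every sub-model estimable; a raw-variable
mode is available through the underlying functions.  PCA components are
sign-anchored (largest loading positive) for reproducibility across BLAS
builds.

## Piecewise SEM

Local models are OLS only (no distribution families are required by the
design); collinear-but-nonsingular predictors are retained with a
condition-number warning (> 1e6), exactly singular fits error naming the
node.  The basis set takes, for each non-adjacent pair with u
topologically before v, the claim u ⟂ v | parents(u) ∪ parents(v),
tested as the p-value of u added to v's parental regression; Fisher's
C = −2Σ ln p on 2k df, with C = 0, p = 1 for a saturated DAG.  Effects
are decomposed by directed-path enumeration; standardized coefficients
are invariant to affine rescaling of any variable.  The shipped default
DAG (Env → MA/Div/Indicator/PP; drivers → SNP/Cycling; SNP, Cycling,
PP, MA, Indicator → EMF) is data, not code — the motivating model's
exact edge set is not published — and composites are PCA-based, flagged
in output.

## Problem sizes and numerical choices

Calibration checks use 500 replicates at reduced sizes (Kruskal–Wallis
at 3 × 12 observations, where the χ² reference for H is accurate;
IndVal at 4 taxa × 8 samples with 199 permutations; Mantel at 7 objects
with 99 permutations; d-separation claims at n = 30).  Recovery checks
use 50 default-size studies for indicators (sensitivity measured over
planted taxa that survive the count filter — undetectable taxa cannot be
recovered), n = 5000 for SEM coefficients (±0.05), 200 studies for the
effect-ordering rate, and 100 studies at 12 plots/group for the
VPA/LMG driver-ranking rate — R² decompositions on 18 plots are too
noisy for a stable ranking guarantee even with clear population
separation, so the package states the larger size as its chosen
condition for that check.  Permutation p-values are never exactly zero
by construction.  The exact-Gram construction in the tests builds
columns whose *sample* covariance equals a target matrix, so closed-form
partial-correlation and LMG values are reproduced to 1e-10 without
asymptotics.

## Known limitations

Min–max scaling is sensitive to outliers at small n; no weighted or
turnover multifunctionality; Bray–Curtis and Spearman networks do not
address compositionality (no CLR / SparCC variant); FDis uses truncation
rather than Cailliez correction; the synthetic generator does not model
read errors, chimeras, spatial autocorrelation or phylogenetic signal in
traits, so passing tests demonstrate correctness of the statistics and
recoverability under the stated generative model, not performance on
real sequencing data.
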