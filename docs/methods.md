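# Methods

This note documents the models implemented in `traitshift`, the conventions
and numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## The causal model and its estimators

All inference is *within region*: regions are assumed internally homogeneous
in climate and soil, so broad-scale confounders are closed by design rather
than by adjustment. The assumed directed acyclic graph over the four
disturbance variables is

```
forest_loss ──► n_patches ──► edge_density ──► degradation ──► outcome
      │______________│______________▲               ▲
      │______________│______________________________│
      └──────────────────────────────────────────────────────► outcome
```

(forest loss raises patch counts; both raise edge density; all three raise
local degradation; all four can shift the community outcome). The *total*
effect of an exposure is identified by adjusting for its ancestors only —
mediated paths stay open. `backdoor_controls` derives the sets from the
graph (ancestors of the exposure), which for the default graph gives the
familiar ladder: nothing for forest loss, forest loss for patches, and so
on. The estimator is OLS on standardized variables, so a coefficient is the
outcome shift (in sd) per sd of exposure; significance is a t-based 95% CI
excluding zero, with no multiplicity correction across the effect grid
(corrected inference is the dc-CA screen's job).

Transform conventions: forest loss and patch counts are `log1p`-transformed
(zeros occur in fully forested buffers), seed mass is `log`-transformed
(strictly positive); predictors are z-scored within region × scale and
outcomes within region. Zero-variance variables are dropped with a warning
rather than fitted.

A companion *predictive* model (`fit_predictive_model`) selects among the
2⁴ subsets of the four exposures by AICc, approximating selection for
out-of-sample accuracy. It answers a different question (how much variation
the disturbance set explains) and must not be read causally. AICc admits a
pure-noise regressor with probability ≈ P(χ²₁ > 2) ≈ 0.16, so on data where
one exposure is generative the exact model is chosen in roughly 60% of
runs — that is a property of information criteria, not a defect of the
implementation.

## Spatial filtering

Residual spatial autocorrelation is handled with Moran's eigenvector maps.
Four candidate spatial weighting matrices are built (Gabriel graph and
minimum spanning tree, each with binary weights or weights decreasing
linearly in distance, `w = a·(1 − d/dmax)`); MEMs are eigenvectors of the
doubly centred matrix with positive eigenvalues, ordered by Moran's I. The
screen tests the model residuals' global Moran's I by permutation (one-sided
for positive autocorrelation, 199 permutations by default), Šidák-corrected
across the four candidates (α_c = 1 − (1−α)^(1/4)). Within significant
candidates, eigenvectors are added greedily — each step takes the vector
whose removal most reduces residual Moran's I — until the residual test is
non-significant; the candidate needing the fewest vectors wins. With
white-noise residuals this selects nothing in ≥ 95% of runs by
construction of the family-wise correction.

Duplicate plot coordinates are a hard error (jitter is refused): the
connectivity graphs are undefined at zero distance and silently perturbing
coordinates would change every downstream test.

## Community metrics

CWM is Σwᵢtᵢ/Σwᵢ over species with trait data (pairwise deletion with the
coverage reported; no imputation). The weighted percentile is the
step-function inverse of the cumulative weight with averaging at exact
jumps, which is *identical* to the empirical percentile (numpy's
`averaged_inverted_cdf`) of the stem-expanded vector — chosen precisely
because it admits an exact brute-force oracle. Percentiles are computed on
the abundance-weighted distribution; an unweighted species-level variant
can be obtained by passing unit abundances. The degradation proxy is the
inverse of basal area per sampled area, `plot_area / basal_area`.

Plot inclusion per trait follows two abundance-coverage rules, both
inclusive at the threshold: ≥ 50% of stems with species-level trait data
and ≥ 80% with species-or-genus-level data (the genus fallback requires a
`genus` column in the trait table; without one the 80% rule uses
species-level coverage and logs that). Rules are evaluated per trait, the
stricter of the two readings of a joint-versus-per-trait ambiguity.
Species-level analyses use species occupying ≥ 5 plots within a region.

## Niche null model

The null redistributes a species' abundance vector uniformly across its
region's plots and recomputes the niche centroid; 10,000 iterations at
paper scale (1,000 in desk-scale defaults: the Monte Carlo s.e. of the
quantile position at 10,000 iterations is ≤ 0.005, and classifications are
stable across seeds except within ~0.02 of the 0.95 boundary). Winners and
losers are strict exceedances of 95% of null values; ties count as
non-exceedance (conservative); a degenerate null (sd = 0, e.g. a species
present everywhere with equal abundance, or detected by a relative
tolerance of 1e-10 against float summation noise) classifies as neutral
with undefined SES. SES uses the null sd (not a robust spread), and the
trait regressions use SES as response (raw SNC available via a flag); the
permutation scheme is per species, not a joint matrix shuffle with fixed
row and column totals — the latter is a different null that is noted but
not implemented. Each species draws from its own RNG stream derived from
the global seed and a hash of the species/region pair, so adding species
leaves earlier results untouched.

## dc-CA and the max test

Abundances are divided by plot totals first, so plots enter with equal
weight regardless of plot size; CA row/column weights and the χ²-scaled
residual matrix Q_ij = (p_ij − r_i c_j)/√(r_i c_j) follow from the
normalized table. The doubly constrained solution projects Q onto
row-weighted and column-weighted orthonormal bases of the predictor and
trait spans and takes an SVD of the core; eigenvalue k is the squared
weighted fourth-corner correlation of the k-th composite pair, so all
eigenvalues lie in [0, 1]. This two-step weighted-regression form was
chosen over iterative alternation because each ingredient is directly
checkable (the package tests it against a closed form for single pairs, a
brute-force grid over unit-variance composites, and vegan's CCA in the
unconstrained-species limit). Collinear trait or predictor columns raise a
named error with the condition number; a term whose variation is fully
absorbed by the covariates is reported with statistic 0 and p = 1 rather
than an error, so duplicate terms in a sequential screen behave sensibly.

The max test takes the larger of two permutation p values: plots permuted
(within covariate strata — within regions when region is the covariate) and
trait rows permuted. The test statistic is the first eigenvalue by default
(trace via a flag). For sequential terms the conditioning predictors join
the covariates; permuting the term's values within region strata while
holding continuous conditioning variables fixed is exact only for factor
covariates and approximate otherwise, which is the standard compromise for
this design. The term screen Bonferroni-adjusts p_max across all tested
terms and ranks terms by their marginal fourth-corner eigenvalue.

## The synthetic generator

The generator encodes the study conditions the pipeline targets: six
regions × 45 plots, a 1,207-species pool with lognormal baseline abundances
(sd 1.5, giving hyperdominance — the top decile of species holds a majority
of stems), three nested buffer scales sharing one latent forest-loss field
with scale-specific noise (cross-scale correlation ≈ 0.95–1), and the DAG
above as a linear-Gaussian structural model on standardized latents.
Observation equations map latents to data: forest loss is log1p-affine in
its latent (median ≈ 13% loss), patch counts are a rounded log-linear
function of log loss (the only deviation from exactness in the noise-free
limit is integer rounding), edge density and the degradation index are
affine with ranges chosen to make clipping negligible (basal areas ≈ 13–38
m² ha⁻¹). Basal area adds 2% multiplicative measurement noise so the
degradation index is recovered, not restated.

Traits: wood density truncated-normal on (0.1, 1.2) g cm⁻³ (mean 0.58, sd
0.15), seed mass lognormal (median 80 mg, log-sd 1.5), LMA truncated-normal
(90 ± 25 g m⁻², > 20), maximum height lognormal (median 20 m, log-sd 0.4),
and a dispersal syndrome drawn from a multinomial logit on log seed mass
that enriches synzoochory among large seeds and endozoochory among small
ones. These magnitudes are field-plausible choices, not estimates of any
real region — the generator defines scenarios, it does not fit data.

Community assembly is exponential trait sorting: log expected abundance of
species j in plot i adds, per sorted trait, (standardized trait)ⱼ × gᵢ with
a unit-variance plot gradient g = β·z(forest loss) + δ·z(degradation) +
residual. Because the tilted mean of a standard normal trait under
exp(g·t) is exactly g, the standardized CWM slope on the standardized
exposure equals β + δ·(loss→degradation total effect) in closed form; this
is what `SyntheticTruth` records, via path sums over the standardized
structural coefficients. Truth distinguishes the *causal* total effect
(zero for landscape variables measured at buffers other than the sorting
scale, which cause nothing downstream) from the backdoor estimator's
probability limit (attenuated by cross-scale correlation); the two coincide
at the sorting scale. Counts are Poisson around expectations rescaled to
~120 stems per plot (negative binomial via a flag); Poisson and
finite-pool noise attenuate recovered effects by ≲ 5% at these sizes, which
the recovery tolerances absorb. Default sorting (wood density −0.5, seed
mass −0.5 on forest loss; −0.25/−0.15 on degradation) encodes a
forest-loss : degradation importance ratio of about two.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: regional floras are draws from one global
pool (no biogeographic turnover), traits are mutually independent apart
from the seed-mass–syndrome link, sorting is exactly log-linear with no
interactions or thresholds, landscape structure is statistical rather than
geometric (no rasters, patch shapes or matrix types), and there are no
temporal dynamics, dispersal limitation mechanisms or observation errors in
counts. Spatial autocorrelation (exponential-kernel Gaussian process on the
loss field) is off by default and exercised separately.

## Numerical and scale choices

Desk-scale defaults (1,000 null iterations, 199 permutations) keep a full
six-region run around twenty seconds and the complete validation suite under
a minute; `--paper-scale` restores 10,000/999. The validation suite sizes
its simulations accordingly: 100-seed recovery runs use one region × 60
plots × 300 species; the path-sum check uses 800 plots where the bias
tolerance is 0.05; permutation calibrations use 200 simulated datasets of
30 plots × 40 species. Eigen-decompositions use dense LAPACK routines
(plot networks here are hundreds, not tens of thousands, of sites);
orthogonality and closed-form identities are enforced at 1e-8–1e-12,
Monte-Carlo quantities at their binomial or KS tolerances.

## Limitations

Inference is conditional on the assumed DAG (which has no testable
implications within this variable set); no sensitivity analysis for
unobserved within-region confounding is provided. The dc-CA reports
fixed-effects within-region relationships; region-interaction terms can be
added as predictors but random-effect formulations are out of scope, as are
Canoco file formats, detrended variants, functional-diversity indices,
trait imputation and GIS processing of land-cover rasters (the pipeline
consumes the resulting landscape table).
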