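# Methods

`longgut` re-implements, as a tested library, the statistical core of a
longitudinal gut-microbiome analysis: a small number of wild primates
(five, in the design emulated here) sampled a few times per month across a
year that splits into a cold dry season (April–October) and a warm rainy
season (November–March), with monthly feeding and affiliation rates (min/h)
and monthly precipitation (mm) as covariates. This note documents the
models, the conventions chosen where several exist, the synthetic-data
generator, and the numerical decisions.

## The compositional mixed model

Counts are converted to per-sample proportions; entries below 0.5% of a
sample are removed (guarding against index hopping), the remainder is
renormalized, and the centered log-ratio (CLR) transform is applied per
sample: `clr = ln p − mean(ln p)` over that sample's retained taxa. Removed
(sample, taxon) pairs are *absent* from the long table rather than zero —
the model simply lacks those observations, which avoids `log 0` without
imputation.

The response `clr(s, t)` for sample `s` (of individual `i`) and taxon `t`
is modelled as a Gaussian LMM with fixed effects for fruit, leaf, and
flower feeding rates, affiliation rate (test predictors), and mean monthly
precipitation (control), and random structure

    (1 | sample) + (1 + all predictors || individual)
    + (1 + all predictors | taxon) + (1 + predictors except flowers | taxon:individual)

where `|` denotes correlated and `||` uncorrelated components. The
scientifically crucial terms are the random slopes within taxon: they carry
the taxon-specific responses to diet and social behavior. Predictors enter
on their natural scales (a `z`-scoring flag exists); the alpha-diversity
model below z-scores, matching the different conventions of the two
analyses.

### Inference by within-sample taxon-label permutation

Because the CLR values of a sample are dependent by construction, slope
significance is assessed by permutation: within each sample the taxon
labels of the observations are shuffled, which preserves the full
covariate structure and the multiset of responses per sample while
destroying any taxon–covariate association. The test statistic is
`logLik(full) − logLik(reduced)` under ML; the full-null reduced model
removes all test-predictor slopes from the within-taxon term (precipitation
retained), and per-predictor reductions remove one slope each. The observed
data counts as one permutation of `M`, and
`p = #{statistic ≥ observed} / M`, flooring at `1/M` (0.001 at M = 1000).
One shared permutation sequence serves all reductions — cheaper and valid,
since each reduction is a separate test.

Two implementation rules matter for validity:

- **Every refit cold-starts from the same data-independent point.** The
  statistic must be the identical function of each relabelled dataset.
  Warm-starting permuted refits from a neighbouring optimum measurably
  biased their statistics low in null simulations (type-I error ≈ 0.26 at
  α = 0.05, against ≈ 0.10 with cold starts over 50 null replicates at the
  reduced calibration configuration), because refits started near a
  variance boundary under-explore. Warm starts are therefore not used.
- Non-converged refits are dropped with a warning; if more than 5% fail the
  test aborts rather than report a silently corrupted p-value.

### What is identifiable in composition

A covariate effect common to all taxa shifts every latent log-abundance
equally, so it cancels exactly in the softmax and again in the per-sample
CLR centering: *compositional data carry no information about a common
fixed effect*. The identifiable signal is the taxon-specific slope
contrasts — `(β + b_t) − mean_t(β + b_t)` — whose spread is the slope SD
`τ`. Consequently the synthetic generator's default plants `β = 0` and a
nonzero `τ` for the fruit slope, and parameter-recovery checks compare the
fixed-effect estimate against its identifiable value (zero) and the
estimated within-taxon slope SD against the planted `τ`. A separate
Gaussian-response check (no compositional link) verifies that the engine
recovers nonzero fixed effects.

The 0.5% abundance filter interacts with strong slopes: observations that
a negative slope effect pushes below the threshold are removed, truncating
exactly the most informative responses and attenuating `τ̂` (≈ 0.068
observed for a planted 0.08 at default conditions). This is a property of
the filtering rule, not the estimator; recovery tests therefore disable
the filter (`min_prop = 0`), and users comparing effect sizes across
filter settings should expect mild attenuation under the 0.5% rule. A
much smaller artifact of the same kind persists even without the filter:
zero counts (≈0.06% of entries at the default depth) must be dropped
before the log transform, which shifts the estimated common effect by
~3×10⁻⁴ CLR units per min/h. On the exact latent composition — no
multinomial step — the estimator recovers the identifiable fixed effect
to machine precision.

## The LMM engine

statsmodels' `MixedLM` cannot express crossed grouping factors, so the
engine is implemented here. It fits `y = Xβ + Zb + ε`,
`b ~ N(0, σ²ΛΛᵀ)`, `ε ~ N(0, σ²I)`, with `Λ` block-diagonal over terms and
levels and a repeated per-term factor: a lower-triangular Cholesky factor
for correlated terms (diagonal bounded at zero), a diagonal of relative
SDs for uncorrelated ones. `β` and `σ` are profiled out; the profiled
deviance needs only the sufficient statistics `ZᵀZ, ZᵀX, Zᵀy, XᵀX, Xᵀy,
yᵀy`, so each evaluation costs one Cholesky factorization of the q×q
system (q = number of random-effect coefficients) regardless of the number
of observations. Gradients are analytic (trace term via one q×q solve,
residual term via the conditional modes), verified against finite
differences in the test suite.

- **ML, never REML**: log-likelihood differences across models with
  different random structures are the test statistics, and REML
  likelihoods are not comparable across fixed or random structures.
- **Internal covariate standardization**: slope covariates are divided by
  their SD inside `Z` (precipitation is ~200 mm, rates ~5 min/h; without
  this the relative-covariance parameters differ by two orders of
  magnitude and the optimizer crawls). Estimates, SDs, and BLUPs are
  mapped back to original units.
- **Optimizer**: L-BFGS-B (memory 30) with analytic gradients; diagonal
  factor entries bounded at zero so singular fits (a variance estimated at
  exactly zero) are representable — they are flagged, not treated as
  errors. Starting point: unit relative SDs, zero correlations. A
  line-search abort on a flat boundary is accepted as converged when the
  projected gradient of the deviance is below 1e-2; otherwise up to three
  seeded jittered restarts run before the fit is flagged non-converged.
- **Tolerances**: deviance ftol 1e-9 for reported fits, 1e-7 for
  permutation refits (the statistic needs ~1e-3 absolute accuracy; the
  looser tolerance changes log-likelihoods by ~1e-3 and none of the test
  decisions). Oracle agreement with a dense multivariate-normal evaluation
  is asserted to 1e-6 on instances up to 200 observations, and against R's
  lme4 on a shared instance to 1e-4.

BLUPs (conditional modes `Λû`, in response units) rank taxa by deviation
from the population-average effect; ties in `|BLUP|` break by taxon
identifier for determinism. Collinearity is checked with VIFs on the
fixed-effects-only design; model stability by leave-one-individual-out
refits reporting per-parameter maximum deviations.

## Alpha-diversity models

Faith's PD (branch-length sum of the minimal subtree connecting the
sample's taxa and the root — the convention of the picante default) is
modelled per sample with the same engine: predictors are the three feeding
rates, log-affiliation, and precipitation, all z-scored; affiliation is
log-transformed with an offset of half the smallest positive observed rate
(the source convention leaves the offset unstated) to admit zero months.
Random structure: intercept plus all slopes within individual,
uncorrelated components — with five individuals a full 6×6 covariance is
hopeless, and the composition model's own convention drops within-individual
correlations as unidentifiable. Inference is by likelihood-ratio tests
(ML): full vs. a null without the four test predictors (df = 4), and
drop-one reductions (df = 1) keeping the random structure fixed. The
response is PD or `ln PD` (flag), the latter intended for the active
(RNA-derived) community.

## Distances, ordination, and permutation tests

Faith's PD and weighted UniFrac are computed through scikit-bio (the
normalized UniFrac variant, default on, divides by the maximal attainable
branch-weighted separation, bounding distances in [0, 1]). PCoA is the
classical Gower double-centering eigendecomposition; negative eigenvalues
are reported unmodified (no Lingoes/Cailliez correction) so users can judge
embedding quality. The permutation machinery is authored here because
seeded determinism, strata restriction, and the `(1+b)/(M+1)` convention
are the point; scikit-bio and SciPy serve as independent cross-checks in
the tests.

- `envfit` projects a variable onto the first two ordination axes
  (configurable), permuting values only within strata (individuals) to
  respect repeated sampling. Constant variables get r² = 0, p = 1.
- PERMANOVA is one-way with free label permutation. Note a structural
  property: with maximal group separation the smallest attainable p is the
  fraction of label permutations that recreate the observed partition, not
  `1/(M+1)`.
- Mantel uses Spearman correlation of lower triangles, one-sided
  (positive association), permuting one matrix's rows and columns jointly.
- Procrustes centers both configurations, scales to unit trace, and
  rotates; `m² = 1 − (Σ singular values)²`; protest permutes rows of the
  second configuration with statistic `t = √(1 − m²)`.

## Normalization conventions

- **GMPR**: `r_ij` is the median over shared-support taxa of the count
  ratios (median taken in ratio space); the factor of sample `i` is the
  geometric mean of `r_ij` over all defined `j` including the trivial
  self-ratio, and factors are rescaled to unit geometric mean. Under this
  convention scaling a sample elementwise by `c` scales its factor by
  exactly `c`, and recomputing factors on a normalized table returns 1 —
  properties that fail for small sample numbers under the
  exclude-self, no-rescale variant.
- **Rarefaction** subsamples each sample without replacement
  (multivariate hypergeometric) to a common depth; under-depth samples are
  dropped with a logged warning, mirroring depth-exclusion practice. The
  depth is a required argument — no default is claimed.
- **Rare-taxon grouping** pools taxa below 2% in *every* sample into one
  `rare` column, preserving row sums.

## Differential abundance (W statistic)

For every unordered taxon pair the log-ratio
`ln((count_i + 1)/(count_j + 1))` is modelled with season as fixed effect
and a random intercept per individual (repeated measures); the season LRT
p-values are Benjamini–Hochberg adjusted within each taxon's `m − 1`
tests, `W_i` counts rejections at α = 0.05, and detection requires
`W ≥ ceil(0.7 (m − 1))`. Zero handling is a uniform pseudocount of 1; the
structural-zero and outlier machinery of the original method is a
deliberate simplification, as is the fixed α. Seasonal log2 fold changes
are `log2(mean rainy / mean dry)` per taxon, zero means replaced by the
pseudocount; positive values mean higher in the rainy season.

## The synthetic-data generator

The generator emulates the study design, not the sequencing: 5
individuals × 12 months × 2 samples/month (120 samples), 30 taxa, library
sizes negative-binomial around 10,000 (dispersion 10 — mild, so GMPR has
real unevenness to absorb), a random bifurcating phylogeny with
exponential branch lengths, and precipitation following a concentrated
bump (near 10 mm through the dry season, peaking at ~180 mm in January).
Fruit feeding peaks in the rainy season (February) and leaf feeding in the
dry season (July), both mean 6 amplitude 4 min/h; flowers peak at the
late-dry transition (November), affiliation mid dry season (May); all rates
carry truncated Gaussian noise (SD 1.5 min/h) so they stay non-negative.
The peak phases, the non-sinusoidal rain shape, and the noise scale are
chosen so the five covariates are seasonal but not collinear — with pure
same-period sinusoids any three templates are linearly dependent and VIFs
explode, a degeneracy real behavioral data do not have (observed max VIF
on the default bundle is ~3–5).

Latent log-abundances follow the generative mirror of the analysis model
(baseline + intercepts for individual/taxon/sample/taxon-individual +
per-predictor common, taxon, individual, and taxon-individual slopes +
residual), proportions are the per-sample softmax, and counts are
multinomial — so sample totals are conserved exactly. Effect defaults:
`β = 0` everywhere (see identifiability above), `τ_fruit = 0.08` CLR units
per min/h (a clearly detectable but not overwhelming taxon-specific diet
signal at these sample sizes), intercept SDs 0.1–0.25, residual SD 0.3.
An optional `season_evenness_effect` sharpens rainy-season compositions,
lowering detected richness and hence PD — emulating the reported
dry-season alpha-diversity excess.

What the generator does **not** emulate: taxonomy misassignment, chimeras
or any read-level artifacts, phylogenetic correlation between taxon
effects and the tree, within-month temporal autocorrelation beyond the
seasonal covariates, and real-data zero inflation beyond what the
multinomial induces. Passing recovery and calibration tests therefore
demonstrates correctness of the estimators and tests under the stated
model, not robustness to those real-data features.

## Problem sizes in the shipped tests

The dedicated statistical checks run at the configurations that make them
sharp but affordable: the permutation-floor check at 8 taxa × 30 samples
with M = 1000; type-I calibration at 10 taxa × 40 samples over 50 null
replicates with M = 49 (and 200 replicates at M = 99 for the
distance-based tests); recovery over 20 default-condition replicates. The
end-to-end pipeline demonstration runs the full default bundle with M = 9
permutations — the full composition model is a ~15–20 s ML fit (q ≈ 1075
random coefficients, 43 covariance parameters), so large M is a
cluster-scale exercise; the permutation count only changes the p-value
floor, not the code path exercised.

## Known limitations

- The composition permutation test refits two models per permutation per
  reduction; at full model size this is expensive (see above). A
  score-test approximation would be cheaper but would not replicate the
  source procedure.
- ML variance components are mildly biased downward at five individuals;
  this is inherent to ML (and to the source's model comparisons, which
  require ML) and shared by the reference implementations.
- `m²` and protest operate on the coordinate matrices as given; axes are
  not re-weighted by eigenvalue.
- The ANCOM-style test inherits the pseudocount's sensitivity at very low
  depths.
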