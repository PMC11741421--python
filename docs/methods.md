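# Methods

This note documents the statistical models implemented in `strainepi`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the package's numerical
choices and known limitations.

## Adaptive coverage filtering

**Model.** A species' gene repertoire in a metagenome is only analyzable at
the strain level when coverage saturates gene detection. For each
species-sample pair we compute (i) the number of genes with nonzero
abundance and (ii) the median natural-log abundance of the nonzero
observations (undefined when there are none). Both statistics are
standardized to zero mean and unit variance — they live on incommensurate
scales (counts vs logs), and without standardization the count axis would
dominate the clustering — then clustered with k-means, k = 2, using 10
seeded restarts (best inertia). The cluster whose centroid has the larger
sum of standardized coordinates is labeled *well covered*; exact ties are
broken toward the larger `n_nonzero` centroid, since breadth of coverage is
the primary saturation signal. Samples with zero nonzero observations never
enter the clustering and are labeled poorly covered directly; with fewer
than two clusterable samples everything is labeled poorly covered with a
warning.

The natural log is used for the median statistic; any base yields the same
k-means geometry after standardization. The raw (not log) count is used as
the first coordinate.

**Full gene-table filter.** Three steps, then binarization: a prevalence
filter (genes occurring in fewer than `floor(f·N)` samples, or in more than
`N − floor(f·N)`, are removed; `f = 0.005` by default; counts exactly at
either bound are kept, matching the strict "fewer/more than" reading), the
k-means sample filter, and a second prevalence filter computed at the
post-dropping sample count. Surviving entries are binarized to presence
(abundance > 0). Filtering never increases matrix dimensions and never
modifies surviving abundances before binarization.

## Gene-carriage association

**Per-gene GLMs.** For each non-constant gene,
`outcome ~ covariates + gene_presence` is fit by iteratively reweighted
least squares (statsmodels) with the identity link for continuous outcomes
and the logit link for binary ones, and the Wald p-value of the presence
term is retained. P-values are Benjamini–Hochberg adjusted per species
across that species' surviving genes (hit lists are reported per species),
with hits called by a strict `Q < 0.05` threshold (configurable). Logistic
fits with complete separation are flagged (non-finite coefficient marker)
and excluded from the BH family.

**Joint horseshoe model.** Alternatively all genes enter one model,
`outcome ~ covariates + Σ_g γ_g · presence_g`, with a regularized horseshoe
prior on γ: per-gene half-Cauchy(1) local scales, a half-Cauchy global
scale with τ₀ = p₀/(1−p₀) · σ̃/√n (p₀ = 0.01 expected nonzero fraction;
σ̃ = 2 pseudo-scale for the Bernoulli family), and a Student-t slab
(scale 2.5, 4 degrees of freedom) bounding selected coefficients — the
reference defaults of the regularized-horseshoe construction, since only p₀
is a primary design quantity here. A gene is a hit when its central 99%
posterior interval excludes zero and |posterior mean| exceeds 0.5 on the
link scale (both configurable). Genes with identical presence patterns are
exactly collinear and are collapsed to one representative before sampling,
then expanded with a shared coefficient and a `collinear_group` flag.

## Tree construction from gene presence

Per-species phylogenies are approximated from the filtered, binarized
presence matrix: columns (genes) are mean-centered but not scaled (they
share the 0/1 scale; scaling near-constant columns would amplify noise);
the number of principal components kept is adaptive — up to and including
the first eigenvalue below one tenth of the leading eigenvalue (an
exclusive variant is exposed as a flag); Euclidean distances between sample
scores feed neighbor joining (scikit-bio; negative branch estimates are
clipped to zero with the deficit transferred to the sibling edge, which
preserves path lengths); the unrooted NJ tree is midpoint-rooted (the
PGLMM covariance needs a root and midpoint is the standard neutral choice)
and ladderized (children ordered by descendant-leaf count). The pipeline is
fully deterministic. An option accepts log-abundance matrices in place of
presence matrices.

## Phylogenetic generalized linear mixed models

**Model.** Each sample (tree leaf) receives a random intercept u with
`u ~ MVN(0, σ_P²Ω)`. Ω derives from the rooted tree: Cov(i, j) = branch
length shared on the root-to-tip paths of leaves i and j, standardized to
unit diagonal; for ultrametric trees this equals `1 − d_ij/(2·depth)` with
d the patristic distance. Gaussian family: `y = Xβ + u + ε`,
`ε ~ Normal(0, σ_R²)`. Bernoulli family: `y ~ Bernoulli(logit⁻¹(Xβ + u))`.

**Priors.** β ~ Normal(0, 5); σ_P, σ_R ~ half-Student-t(3, 0, 2.5) —
standard weakly informative choices, exposed as configuration. The default
*regularized* model adds the density increment
`log Gamma(σ_P/σ_R | shape 1, rate 2)`, i.e. an 86% prior chance
(1 − e⁻²) that the ratio is below one, shrinking the phylogenetic share of
variance when the data are uninformative. For the Bernoulli family no
residual scale exists, so the ratio term is replaced by
σ_P ~ half-Student-t(3, 0, 1).

**Sampling.** The posterior uses a non-centered parameterization
u = σ_P·L·z with L the Cholesky factor of Ω (after symmetric eigenvalue
clipping at zero and a 1e-8 diagonal jitter when needed), scale parameters
on the log scale, and the package's NUTS sampler: multiplicative
dual-averaging step-size adaptation targeting 0.8 acceptance, windowed
diagonal mass-matrix estimation, maximum tree depth 10. Defaults are 4
chains × (1000 warmup + 1000 draws). Any split-R̂ above 1.01 or any
post-warmup divergence attaches a prominent non-convergence warning to the
fit. Every stochastic operation takes an explicit seed; per-chain seeds are
spawned from it and recorded.

**Phylogenetic R².** Per-draw `R² = σ_P²/(σ_P² + σ_R²)` (Gaussian family
only), summarized by the posterior mean and central 95% interval.

**Model comparison.** The PGLMM is compared with a base GLM (same
covariates, no tree term) by leave-one-out expected log pointwise
predictive density. Because the leaf effects make the raw pointwise
likelihoods unstable under importance sampling, the left-out leaf effect is
first integrated out analytically under its conditional law
`u_i | u_{−i} ~ Normal(Ω_{i,−i}Ω⁻¹_{−i,−i}u_{−i}, σ_P²(1 −
Ω_{i,−i}Ω⁻¹_{−i,−i}Ω_{−i,i}))` — in closed form for the Gaussian family and
by 21-node Gauss–Hermite quadrature for the Bernoulli family — before
Pareto-smoothed importance weighting (arviz `psislw`). Samples with Pareto
k > 0.7 are listed in a diagnostic warning. The base model is scored by
standard PSIS-LOO. The difference is summarized as
`elpd_diff ± se_diff` with `se_diff = sqrt(n · var(pointwise diffs))`; the
positive-call rule is `elpd_diff − 2·se_diff > 0` (the multiplier is
configurable; the 2-SE rule is one consistent choice among common
conventions). On small problems (n ≤ 8) the integrated-likelihood LOO
agrees with exact leave-one-out refitting within Monte-Carlo error (tested).

## PERMANOVA comparator

The distance-based comparison method: Gower centering
`G = −½·J·(d∘d)·J`, `R² = tr(HGH)/tr(G)` with H the hat matrix of
intercept + covariate, a pseudo-F from the R² partition, and a permutation
p-value `(1 + #{F_perm ≥ F_obs})/(1 + n_perm)` with covariate permutation
(residual permutation under the intercept-only reduced model). The
simulation study uses the patristic distance matrix of the simulated tree
as input. One canonical variant is implemented. Its pseudo-F matches
scikit-bio's PERMANOVA exactly on grouping designs (tested), and its null
p-values are uniform. When phylogeny causes the outcome, the PERMANOVA R²
systematically underestimates the generative σ_P²/(σ_P²+σ_R²) — the
behavior the comparator exists to demonstrate.

## Pathway-carriage model

`log10(pwy_abd) ~ log10(species_abd) + (1|pwy) + (0+group|pwy) + intercept`.
Zeros are discarded (the model works in logs; a censored-zero variant was
deliberately omitted as adding computational cost without practical
benefit). Pathway intercepts are partially pooled, Normal(0, σ_int) with
σ_int ~ half-t(5, 0, 2.5); group effects are pooled independently of the
intercepts, Normal(0, σ_effects) with the deliberately aggressive
σ_effects ~ Exponential(3) (prior mass P(σ_effects < 0.25) = 1 − e^−0.75 ≈
0.53), encoding that few pathways differ between groups. The global
intercept has a Student-t(5, EM, 2.5) prior where EM is the empirical mean
of the retained log10 pathway abundances (the formula's "intercept" is read
as a sampled global intercept with an EM-centered prior, the interpretation
consistent with scale-parameter positivity elsewhere); the species slope is
Normal(1, 1); the residual scale half-t(3, 0, 2.5). Scale priors written
t(ν, 0, s) are half-Student-t truncated to positives. Pathways with fewer
than 3 retained observations are dropped with a warning.

**Hit rule** (all three required): 98% posterior interval of the pathway's
group effect excludes zero; |posterior mean| > 0.25 (10^0.25 = 1.778…,
reported as a 1.78-fold change); posterior mean species slope positive.
Hit calling is a pure function of the stored draws. The group variable is
coded 0/1 and effects are on the log10 scale.

## Synthetic-data generators

**Gene profiles.** Species log abundance per subject is Normal(μ=0, σ=2)
on the natural-log scale — a configurable stand-in preserving the
log-normal shape of fitted stool-survey presets, whose feature-level
parameters are not public; σ=2 is a realistic cross-sample spread for a
prevalent gut species. Genes are carried independently with probability
0.5 per subject. Disease log-odds = intercept + 1·(number of carried risk
genes) + optional standardized-species-abundance effect, with the intercept
centering baseline prevalence at ~50%; subjects are generated until 200
cases and 200 controls (defaults) are reached. Gene log abundance = species
log abundance + skew-normal(location 0, scale 1, shape −1) noise (unit
slope on species abundance). A random 25% of subjects have all gene log
abundances shifted by −4 ("poorly covered"). Each observation is zeroed
with probability `1/(1 + exp(a − m))` — a logistic in the log abundance
centered on the gene's median carried log abundance with growth rate −1 —
so an observation at its gene's median is zeroed half the time.

What this does **not** emulate: multi-species competition and
compositionality, feature-specific abundance distributions, read-level
noise, or linkage between genes. Passing tests therefore demonstrate
correct statistical behavior under the stated generative structure, not
performance on any particular real cohort.

**Phylogenetic outcomes.** A random binary topology by recursive random
splitting with Uniform(0, 1) branch lengths; Ω from the tree; outcome =
MVN(0, σ_P²Ω) + MVN(0, σ_R²I). The evaluation grid uses six evenly spaced
values per axis — n ∈ {10, 98, 186, 274, 362, 450}, σ ∈ {0, 0.418, 0.836,
1.254, 1.672, 2.09} (endpoints fixed, even spacing chosen) — minus the six
points with both noise scales zero, leaving 210 points.

**Pathways.** The carriage model run generatively: pathway intercepts
Normal(0, 1), unit species slope, group Bernoulli(0.5), a configurable
spiked effect in 3 of 30 pathways, residual scale 1, n = 400 samples by
default, abundances exponentiated back to the linear scale.

All generators are bit-reproducible given their seed.

## Problem sizes used by the built-in checks

The package's own validation suite runs the full estimation paths at
reduced sizes chosen to keep the suite fast while preserving the qualitative
comparisons: PGLMM R² recovery uses 5 replicates per condition at n = 450
and n = 10 with 2 chains × (400 + 400) draws; the null ELPD calibration
uses 10 replicates at n = 100; the pathway error rates use 5 replicates per
spike level with 2 chains × (300 + 300); the coverage-filter accuracy uses
20 replicates at the full 400 × 1000 design; the PERMANOVA calibration uses
200 replicates with 999 permutations. Library defaults remain 4 chains ×
(1000 + 1000).

## Numerical choices and degenerate inputs

- Scale parameters are sampled on the log scale with Jacobian terms
  included; all hand-derived gradients are verified against central finite
  differences in the test suite.
- Ω PSD repair: symmetric eigenvalue clipping at zero plus 1e-8 jitter,
  then re-standardization to unit diagonal.
- NJ negative branch lengths: clip-and-transfer (scikit-bio convention).
- BH uses the running-minimum convention and mergesort (stable) ordering.
- All-zero samples, all-zero pathways, constant genes and constant
  covariates are handled explicitly (markers, warnings, or errors as
  documented per function) rather than producing NaNs downstream.
- Abundance units are used as given (relative abundance or copy number);
  unit handling is delegated to the caller.

## Known limitations

- The gene models treat genes as independent or as a sparse mixture; a
  species with an outcome-confounded subclade will show many collinear
  gene hits (the PGLMM on a gene-profile tree helps detect this situation).
- The PGLMM supports a single tree-derived covariance; secondary covariance
  structure (e.g. cohort relatedness) is not modeled.
- The pathway model supports binary groups only, and discards zeros.
- PERMANOVA is implemented in one canonical variant (covariate permutation
  under the reduced model); kernel-based score tests are out of scope.
- The horseshoe model's funnel geometry can leave marginal split-R̂ values
  above 1.01 at small draw counts; the fit carries a visible warning when
  this happens and more draws resolve it.
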