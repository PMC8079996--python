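# Methods

This note documents the models implemented in `lifecube`, the estimators and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Dimensionless metrics

For each species with complete components we compute

- `LRE = litter_size × litters_per_year × mass_at_independence / adult_mass × adult_lifespan`
- `RRL = adult_lifespan / female_maturity_age`
- `ROS = mass_at_independence / adult_mass`

with `adult_lifespan = max_longevity − female_maturity_age` by default.
Maximum longevity stands in for mean adult longevity because that is what
trait databases reliably report; the subtraction is the reading consistent
with "time from maturity to death". A `raw_longevity` mode is available for
sensitivity runs. Records with `maturity ≥ longevity` are flagged and
excluded, never passed through. Missing components make a metric undefined
(`None`/absent), never zero, and a species enters the metric table only when
all three metrics are computable. All four analysis axes are natural logs.

Amphibian sources report a *maximum* adult mass; by default we use it
directly (`max_mass`). The alternative `mean_mass_from_svl` converts minimum
and maximum snout–vent lengths with user-supplied power-law allometries
`mass = a·svl^b` (group-specific for frogs and salamanders; the coefficients
are not bundled because no universal values exist) and averages the two
masses.

Merging a primary and a supplementary table follows strict precedence:
primary values always win, gaps are filled from the supplement, and
supplement-only species are appended whole, with `<field>_source` provenance
columns recording where each value came from.

## Trees and covariances

Trees are rooted, dated (branch lengths in Myr) and stored in a flat array
form. The Brownian tip covariance is `C_ij = ` shared root-to-MRCA path
length. Model covariances are expressed as *branch-length transforms* so a
single Brownian pruning pass evaluates every model:

- **λ (Pagel)**: off-diagonals scaled by λ; as a tree, all branches ×λ with
  `(1−λ)·depth` added to each terminal branch. Domain [0, 1], which keeps
  the matrix positive semi-definite on any tree.
- **κ (Pagel)**: every branch length `b → b^κ` (with `0^0 := 0`), κ ∈ [0, 3];
  κ = 0 is the speciational limit.
- **OU (stationary)**: on an ultrametric tree of height `T`,
  `C_ij = e^{−2α(T−s_ij)}(1−e^{−2α s_ij})/(2α)`. This is increasing in the
  shared path `s_ij`, so it is again a tree covariance with node depths
  `g(s) = e^{−2αT}(e^{2αs}−1)/(2α)`; the α→0 limit is Brownian motion. OU is
  defined only on ultrametric (time-calibrated) trees here; the overall
  variance scale is carried by σ².

The supertree is built by calibration arithmetic, not congruification: given
ultrametric clade trees and pairwise divergence ages, clades are joined on a
ladder backbone in a user-supplied nesting order (default
Amphibia,(Mammalia,(Reptilia,Aves)) with ages 352/319/280 Myr); each stem
branch is attachment age minus crown age, and within-clade branch lengths
are untouched. Newick serialization uses `repr` floats, so write/parse round
trips are exact.

## Likelihood engine and model fitting

All Gaussian tree likelihoods go through Felsenstein pruning: child messages
`(mean, variance)` are combined pairwise at each node, accumulating the
normalized contrast terms; polytomies combine sequentially (exactly, since
each combine reduces the lineage count by one). For unit rate the pass
yields the log-determinant, the GLS mean `ẑ₀` (the root message mean) and
the quadratic form, so for every shape parameter value the root state and
rate are profiled in closed form: `ẑ₀ = m_root`, `σ̂² = Q/n`. Equality with
the dense multivariate-normal density is part of the test suite (1e-8 on
random trees of up to 12 tips).

Shape parameters are found by bounded Brent search: λ ∈ [0, 1], κ ∈ [0, 3],
`ln α ∈ [ln(1e-8/T), ln(100/T)]`, tolerance 1e-8, with the bounds themselves
checked afterwards because bounded Brent can miss boundary optima. Fits are
maximum likelihood (not REML) so AIC = 2k − 2logL is comparable across
models; ties in model selection go to fewer parameters, then the fixed order
BM < λ < κ < OU. A flat shape-parameter profile (e.g. κ on a tree whose
branches are all equal) is flagged as unidentifiable rather than hidden.

A known statistical property, visible in the `bm_selection_rate` the
acceptance script reports: on data truly generated by Brownian motion, the
richer nested models (κ, OU) each win the AIC comparison at roughly the
χ²₁-tail rate expected for a one-parameter extension, so plain-AIC selection
picks the generating model in substantially fewer than all replicates. This
is inherent to AIC on nested models, not an engine defect; the strong-OU
selection rate is near one.

## Phylogenetic signal

λ is estimated by ML and the p-value comes from a tip-shuffling permutation
test with statistic `LR = 2(logL(λ̂) − logL(λ=0))`:
`p = (1 + #{LR_perm ≥ LR_obs})/(n_perm + 1)` (default 999 permutations,
seeded), so the smallest attainable p is 1/1000. A likelihood-ratio χ² test
was deliberately not used as the default because the permutation floor is
distribution-free and the null distribution of λ̂ is boundary-affected. On
ultrametric trees the permutation sweep is evaluated on a 101-point λ grid
in the eigenbasis of `C` (where `C_λ` is simultaneously diagonalizable),
which makes 999 permutations effectively free; the observed λ̂ reported is
Brent-refined. Constant traits return a degenerate flag, not a number.

## PGLS

`β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` with `V` the correlation structure of the chosen
transform (by convention, the best-AIC model of the *predictor's* — body
mass's — evolution, with its fitted shape parameter reused); the scale of
`V` is profiled out. Standard errors use `σ̂²_resid = RSS_V/(n−2)` and
two-sided t tests on n−2 degrees of freedom. With a λ = 0 transform on an
ultrametric tree PGLS is exactly OLS; with `V = C` the slope equals the
independent-contrasts regression through the origin (both are test
oracles).

## Multivariate PGLS with measurement error

Responses `Y = (log LRE, log RRL, log ROS)` share one Pagel's λ; the tip
covariance of response pair (k, l) is `R_kl·C_λ`, plus `e_k·I` on the
diagonal pairs when measurement error is estimated (the recommended
default). The likelihood is maximized jointly over (λ, R, e) with the 2×m
coefficient matrix profiled by GLS inside the objective; R is parametrized
by its Cholesky factor (guaranteeing PSD) and e on the log scale, optimized
by L-BFGS-B. On ultrametric trees `C_λ = U(λd + (1−λ)T)Uᵀ` shares the
eigenbasis of `C`, so the nm-dimensional likelihood factorizes into n blocks
of size m×m and each evaluation is O(n·m³). Evolutionary correlations are
`r_kl = R_kl/√(R_kk R_ll)`. Complete cases only; no imputation. Per-response
λ is out of scope (one shared λ, the convention of multivariate phylogenetic
GLS with a common signal structure).

## Ancestral states

BM ancestral estimates use two-pass belief propagation: the pruning downpass
gives each node's below-subtree message, an uppass folds in the rest of the
tree (precision-weighted, with a flat message at the root), and each node's
estimate combines the two — equal to the conditional expectation under the
dense covariance algebra, with the root estimate equal to the GLS
phylogenetic mean. Tip states pass through unchanged.

## Cross-clade comparisons

Because the splits among the four classes are ancient relative to
within-class divergences, classes are treated as independent groups:
one-way ANOVA per log metric plus Tukey HSD (studentized-range adjustment)
on the natural-log values, delegated to scipy/statsmodels.

## Hypervolumes

A clade's hypervolume is the region where its Gaussian KDE (equal-weight,
diagonal bandwidth) exceeds the threshold `t` enclosing q = 0.95 of
probability mass. Bandwidths default to Silverman's rule per dimension,
`b_j = (4/((d+2)n))^{1/(d+4)}·sd_j`. The estimator: draw N = 1e5 points
from the KDE itself, set `t` to the (1−q) quantile of their densities, and
average `1{f ≥ t}/f` — unbiased for the Lebesgue volume of the thresholded
region, with no space-filling heuristics, so results are exactly
reproducible from the seed. Intersections are importance-sampled under the
pooled mixture `(f₁+f₂)/2`, drawing half the points from each side with
streams derived from each hypervolume's *own* label, which makes Sorensen
similarity `2V∩/(V₁+V₂)` exactly symmetric in its arguments. Monte-Carlo
overshoot is clipped (`V∩ ≤ min(V₁,V₂)`, ratios to [0, 1]). This is a
reproducible approximation of the point-process hypervolume methodology,
documented as such, not a clone of any existing implementation; volumes are
in log-unit^d and are meaningful relative to each other. Zero-variance
dimensions are an error (jitter or drop them); groups smaller than d+1
points are skipped with a warning.

## Synthetic data

The generator emulates the *structure* of compiled comparative datasets:
per-clade pure-birth trees rescaled to realistic crown ages (Amphibia 320,
Reptilia 205, Mammalia 165, Aves 100 Myr), log body mass under a
clade-specific model (OU for the ectotherm clades, λ for the endotherms,
matching the qualitative finding such analyses report), and log metrics as
linear responses to log mass plus correlated phylogenetic residuals
(λ = 0.9, per-metric sd 0.45–0.6 at the tips, correlation matrix with
LRE–RRL 0.6, LRE–ROS 0.58, RRL–ROS 0) plus small iid measurement error
(variance 0.02). Default species counts are 113/491/842/171 for
Amphibia/Reptilia/Mammalia/Aves; default slopes are LRE −0.17, RRL 0.074,
ROS −0.38 — magnitudes typical of published comparative estimates, so
recovery tests run at realistic effect sizes.

Raw tables are produced by inverting the metric formulas with the
convention `litters_per_year = 1` (four raw fields map to three metrics, so
one convention is needed for an exact round trip): maturity is drawn from a
clade-level lognormal, `longevity = maturity(1 + RRL)`,
`independence mass = ROS × mass`, `litter = LRE/(ROS × maturity × RRL)`.
Recomputing the metrics from the raw tables therefore reproduces the
generating values to floating-point accuracy, which is the pipeline's
round-trip oracle. Reptile records are split between a primary and a
supplementary table (and some moved wholly to the supplement) to exercise
the merging rules; configurable per-field missingness masks values in both.
OU traits are simulated from the exact stationary covariance, never by
Euler stepping.

What the generator does *not* emulate: real taxon-sampling biases,
taxonomic synonymy, the exact column vocabularies of the source databases,
non-ultrametric trees, heteroskedastic measurement error, or non-Gaussian
trait distributions. Passing tests therefore demonstrate correctness of the
estimators under their assumed models at realistic sizes — not robustness
to every pathology of real compiled data.

## Seeds and reproducibility

The pipeline spawns one seed per stage from the global seed via
`SeedSequence([seed, stage_index])`, recorded in the manifest, so any stage
can be reproduced in isolation. Hypervolume sampling streams derive from
`[seed, crc32(label)]`. Fixed configuration + seed gives byte-identical CSV
outputs.

## Problem sizes

Simulation-recovery tests run at 200 tips (univariate; 50–100 replicates)
and 300 tips (multivariate; 20–50 replicates); the full-pipeline round trip
uses 300 tips per clade over 3 replicate bundles; the acceptance script uses
20–40 replicates per quantity. These sizes put Monte-Carlo error comfortably
inside the assertion tolerances while keeping a full run to a few minutes on
one CPU.

## Known limitations

- Single-optimum OU only; no early-burst or trend models; no phylogenetic
  uncertainty (one fixed tree per run).
- OU requires ultrametric trees; κ on trees with near-zero branches can
  yield ill-conditioned covariances.
- mv-PGLS assumes one shared λ and diagonal measurement error.
- Hypervolume volumes depend on bandwidth and q; only relative comparisons
  across groups built with the same configuration are meaningful.
- Exact-name species matching only (after whitespace/underscore
  normalization); no synonym resolution.
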