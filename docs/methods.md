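# Methods

## Model

`gamcokrige` estimates the expected count λᵢ of a rare health outcome per
site (village) over a fixed study period as the sum of a covariate-driven
local mean and a spatially autocorrelated residual:

    Λ = μ + e,        yᵢ | λᵢ ~ Poisson(λᵢ)

**Stage 1 — local means.** μ is fitted by a Poisson log-link additive
model. Each smooth term is a cubic B-spline basis with exactly `df` columns
(interior knots at quantiles of the training covariate, boundary knots at
its range); linear terms enter as single columns; the geographic location
enters as one tensor-product surface of per-margin cubic bases
(`coord_df` columns per margin, 3 by default). The fit is unpenalized
maximum likelihood via iteratively reweighted least squares. We prefer
fixed-df bases over penalized splines with an effective-df target because
the df is then exact by construction — the df 5–10 sensitivity analysis
varies the actual model dimension rather than a penalty — and because term
Wald tests on an unpenalized fit are standard GLM inference. The cost is
that bases at different df are not strictly nested (knots move), so
in-sample fit is only near-monotone in df (observed dips ≲ 0.001 R²).

**Stage 2 — residual cokriging.** Two residual series are formed on the
count (response) scale, exactly as the two-stage procedure defines them:
the spatial residual εₛ = y − μ̂ and the regional residual εᵣ = y − ȳ
(mean-zero by construction). A linear model of coregionalization (LMC)
represents their direct and cross-variograms on shared structures: a
nugget, a short-range ("local") structure and a long-range ("regional")
structure, each with a symmetric 2×2 coefficient matrix. Fitting proceeds
in three steps: (1) single-structure weighted-least-squares variogram fits
to each series fix the two ranges; (2) the sills of all three curves are
refit on the shared structures (nonnegative WLS for the directs, signed WLS
for the cross); (3) each structure's cross coefficient is clipped to
|b₁₂| ≤ √(b₁₁b₂₂), which makes every coefficient matrix positive
semidefinite and hence the joint covariance valid; clipping is recorded in
`psd_flag`. The spatial residual at a target is then predicted by simple
cokriging (known zero means, the natural choice since both series are
mean-zero; ordinary cokriging with Σλˢ = 1, Σλʳ = 0 is available by flag)
over the nearest neighbours. The combined prediction is
λ̂ = max(μ̂ + ε̂ₛ, λ_floor): the additive combination can fall below zero
while an expected count cannot, so a small positive floor (default 10⁻³)
truncates it.

**Risk inference.** Under the Poisson law, P(≥1 case) = 1 − e^(−λ̂) and the
odds of at least one case against none are e^(λ̂) − 1; a site is a hotspot
when its odds exceed a threshold (default 500, i.e. λ̂ > ln 501 ≈ 6.22).
The marginal moment fit reports the sample mean and variance of the counts
plus an overdispersion score statistic, z = Σ[(y−ȳ)² − y] / √(2nȳ²),
asymptotically standard normal under Poisson sampling, with a one-sided
p-value. This is the package's own dispersion diagnostic — a standard score
test, not a reconstruction of any particular published statistic.

## Supporting procedures

**Covariate extraction.** Area-proportion covariates are the fraction of a
disc around the village point covered by one polygon category, computed by
exact polygon clipping against a 64-segment disc approximation (area error
< 0.1%). Distance covariates are exact Euclidean point-to-polyline
distances. All coordinates are projected planar metres; no CRS handling is
performed.

**Decaying-buffer screening.** For each polygon category the Pearson
correlation between the area proportion and the observed counts is swept
over buffer radii (default 20 m then 100 m steps to 3 km — the endpoints
are the standard protocol, the step is ours). The radius maximising |r| is
optimal (ties to the smaller radius); the category is kept only if
|r| ≥ 0.2 and p ≤ 0.1 there, with p from the t transform on n−2 df.
Zero-variance proportions give an undefined r, recorded as missing and
excluded from the optimum.

**Three-step selection.** Candidates are split by variance inflation factor
(VIF = 1/(1−R²), exact collinearity reported as ∞) into weak (VIF < 5) and
strong covariates; strong ones are grouped by connected components of the
|r| ≥ 0.7 graph (the grouping threshold is ours; configurable). Every
combination of one member per group plus all weak covariates is fitted and
backward-eliminated — dropping the single worst term with p ≥ α = 0.1 per
iteration until all remaining terms are significant — and the combination
with the highest R² wins (ties: fewer covariates, then lexicographic). R²
here and throughout the evaluation is the squared Pearson correlation
between observed counts and fitted/predicted means; deviance explained is
available behind a switch. The per-covariate "variance proportion" is the
drop in model R² (percent) when that term is removed from the final model.
Note a property of backward elimination at α = 0.1: with k pure-noise
candidates the incidentally best-fitting one survives with probability
≈ 1 − 0.9ᵏ, so intercept-only outcomes under the null are a modest
majority, not a near-certainty.

**Evaluation.** Model comparison uses leave-one-out cross-validation with
identical folds across four models: Poisson GLM (all terms linear plus
linear coordinates), universal kriging (planar coordinate trend by OLS plus
ordinary kriging of the trend residuals; order-2 trend available), the GAM
alone, and the combined model. Per fold every stage is refit on n−1 sites,
including the variogram parameters (a flag fixes them from the full data
instead, the common GIS shortcut — note that mode leaks a little
information from the held-out site into the variogram). Metrics: R² as
above, median error, IQR and RMSPE of observed − predicted, and Tukey
box-plot statistics. A fold that fails to fit is recorded as failed and
excluded from the metrics rather than aborting the report; the sample
median and IQR are both always reported because a median error and an IQR
answer different questions about the error distribution. The sensitivity
analysis grids LOOCV R² over smooth df 5–10 and the five variogram families
(spherical, circular, exponential, gaussian, stable) and summarises median,
mean and a 2.5–97.5% interval.

## Numerical choices

- Variogram families use the effective-range convention for unbounded
  models: correlation exp(−3(h/a)^κ) with κ = 1 (exponential), 2
  (gaussian), free in (0, 2] (stable); spherical and circular reach their
  sill exactly at the range.
- Empirical variograms use the Matheron estimator on distance bins of
  `lag_size` (default: the mean nearest-neighbour distance) with bins
  containing zero pairs omitted; WLS fitting weights each bin by
  pair count / h², and the fitted range is capped at 1.5× the largest lag —
  an empirical variogram still climbing at its last lag cannot identify a
  longer range, and uncapped fits destabilise the kriging covariance.
  A flat empirical variogram is returned as a pure plateau and flagged.
- Field simulation is exact Cholesky of the site covariance with escalating
  jitter (up to 10⁻⁶ of the mean diagonal) before failing. Cross-correlated
  pairs are drawn as a = L₁z₁, b = L₂(ρz₁ + √(1−ρ²)z₂): a valid joint
  Gaussian with exact marginals for any ρ ∈ [−1, 1]; with identical models
  and ρ = 1 the draws coincide.
- Kriging systems are solved densely per target with jitter-and-retry;
  kriging variances are floored at zero against roundoff.
- GAM predictions clip the link-scale predictor to the fitted in-sample
  range ± 0.5 (`eta_margin`, disableable): a query in a sparse corner of
  the tensor basis can otherwise blow up through the exponential — in one
  cross-validation fold an unguarded prediction reached ten times the
  largest observed count and single-handedly destroyed the Pearson R².
- IRLS convergence is accepted on the R-style relative deviance criterion
  (|Δdev|/(|dev|+0.1) < 10⁻⁶) when the backend's absolute criterion times
  out on a slow geometric creep in the sixth significant digit.
- The pipeline's defaults widen two estimation settings relative to the
  standalone functions: 24 neighbours (vs 16) so the long-range structure
  has enough sites in the cokriging neighbourhood, and 20 lags (vs 12) so
  the variogram span (~28 km at the default site density) covers the
  regional plateau.

## The synthetic generator

No raw data from the motivating study are deposited, so the generator is
the package's test bed. It emulates: 326 uniformly scattered villages in a
50 km × 45 km projected domain; soil (9 classes) and lithology (6 classes)
polygon layers built as category-labelled Voronoi partitions; polyline
layers (3 rivers, 2 faults, 2 roads, 1 watershed) as jittered chords;
covariates with spatial structure (a fertilizer analogue as a transformed
Gaussian field, distances to the generated polylines, a lithology area
proportion at a 1.5 km buffer) plus inert socio-economic noise covariates;
and a log-scale mean with one monotone-increasing smooth (fertilizer), one
decaying negative smooth (fault distance), one negative linear term
(lithology proportion) and a broad dome-shaped coordinate surface. The
residual field is the sum of two cross-correlated components (ρ = 0.5,
"moderate") with spherical structures at ranges 2425.41 m and 13836.0 m —
the two scales the analysis exploits. Their partial sills (0.10 local,
1.00 regional) follow from reading the study's reported local sill as
nugget-dominated: 0.65 total minus a Poisson nugget ≈ 0.57 leaves ~0.1 of
structured short-range variance, while the regional structure dominates.
Counts are Poisson draws from max(μ + e, λ_floor).

What the generator does *not* emulate: the marginal mean count is ~1.5
cases per village (the motivating study reports ~0.57) — at the lower level
Poisson noise swamps the spatial signal at this site density and every
model collapses toward indistinguishability; villages are uniform rather
than valley-clustered; layers are Voronoi cartoons with no terrain or
hydrology; covariate effects are exactly additive on the log scale with no
interactions; counts are conditionally Poisson with no unstructured
overdispersion beyond what the residual field induces. Passing recovery
tests therefore demonstrate that the estimators recover the structure they
assume, at realistic scale and noise — not that the model is correct for
any particular real region.

On the default configuration the qualitative model ordering is the one the
method predicts: the GAM clearly beats the all-linear GLM (non-linear and
dome-shaped effects), and cokriging adds a further median gain of ≈ +0.02–
0.03 LOOCV R² over the GAM. The gain is modest by construction: honestly
held-out Poisson counts put a noise floor E[λ] under any model's squared
error, and the spatially structured residual share that survives stage 1
is what cokriging can recover. A count-scale residual is also
heteroscedastic (variance ≈ λ), which injects noise into the stationary
kriging system around high-mean clusters; a link-scale residual mode is
deliberately not offered, to keep the two-stage procedure exactly as
defined.

## Known limitations

- Isotropic variograms only; two coregionalized variables only; no block
  kriging; no anisotropy.
- Plain Poisson likelihood (no negative-binomial or zero-inflated
  families); the quasi-likelihood scale is reported but unused.
- LOOCV only (as in the evaluation protocol); no spatially blocked CV, so
  the comparison shares the usual optimism of non-blocked spatial CV.
- The backward-elimination stopping rule is strictly significance-driven;
  stepwise R²-tracking variants are not implemented.
- Extrapolation beyond the training covariate range uses boundary-clipped
  bases (constant continuation) and is flagged, not modelled.
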