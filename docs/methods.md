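# Methods

This note documents the models implemented in `reefpulse`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Survey data model and cover

A photo-quadrat survey is a hierarchy site → depth band (3–5 m or 10–12 m)
→ transect → image → point. The design constants default to 50 scored
points per image and 25 images per transect (1,250 points per complete
transect). Benthic labels form a controlled vocabulary: live coral (genus
level, with *Porites* split into branching, massive, and the encrusting
*Porites rus*, and the octocoral *Heliopora* included), bleached coral,
recently dead coral, turf-overgrown dead coral, CCA-overgrown dead coral,
and non-coral categories (macroalgae, turf, CCA, sand, rubble, other).

Bleaching severity is scored on live, bleached, and recently-dead coral
points; turf- and CCA-dead corals died before the scored event and carry no
severity state. Cover is the fraction of points per category over the
pooled transect (replicate-level pooling is available but not the default,
because the transect is the sampling unit for the downstream site-level
analyses).

The community matrix holds each coral taxon's share of live coral per site.
Rare taxa are filtered on their share of the *pooled* coral observations
across all rows (default threshold 0.5 %), then rows are renormalized; the
filter is idempotent. The *Porites* relative abundance (RA_POR) is the
share of massive *Porites* plus *Porites rus* among live coral points,
consistent with the community-matrix convention.

## Bleaching Response Index

Seven ordered severity categories (normal, pale, 0–20 %, 20–50 %, 50–80 %,
80–100 % bleached, recently dead) receive weights 0–6 on their proportions;
the weighted mean divided by 6 gives BRI ∈ [0, 1]. The index is linear in
the category proportions, so site-level BRI equals the colony-count-weighted
mean of per-taxon BRIs, and any shift of probability mass toward higher
severity increases it. An alternative weighting (1–7 over the same
categories, same divisor) is exposed for comparison with sources that print
that form; it shifts the index by 1/6 and can exceed 1, which is why the
0–6 convention — under which reported community indices fall in the
observed 0.01–0.6 range — is the default. Inputs are proportions; a
percent-scale output switch multiplies by 100.

## Thermal metrics

DHW follows the Coral Reef Watch heritage rule: HotSpot(t) = max(0, SST(t)
− MMM); DHW(t) = Σ over the trailing 12 weeks (inclusive) of HotSpots ≥
1 °C, in °C-week. The MMM is the warmest month of the monthly-mean
climatology over the baseline window (default 1985–2009, the pre-event
span, rather than a satellite-era recentered climatology; configurable).
The first 11 weeks use the available partial window. Window length and the
1 °C inclusion threshold are config keys.

Event metrics over a stated window: maximum weekly SST, maximum DHW, weeks
with DHW > 4 and > 8 (strict inequality by default; inclusive available),
and Alert-Level-I duration operationalized as weeks with DHW ≥ 4.
Historical metrics over the baseline: CV_SST (sd/mean of weekly SST),
σ_wk/σ_mon (sd across years of the annual maximum weekly / monthly-mean
SST), MaxSST_avg, MaxDHW_avg, mean annual counts WkDHW4_avg/WkDHW8_avg, and
fDHW4/fDHW8 (fraction of baseline years whose annual maximum DHW exceeds
4/8 °C-week). Years are calendar years of the week-start date; standard
deviations are sample (n−1) throughout. Series must be weekly; gaps of at
most two weeks are linearly interpolated, longer gaps rejected.

## Population metric and site table

Human disturbance is proxied by Σ village population / along-coast distance
over the designated closest village(s), standardized by the mean across
sites (so the standardized metric averages exactly 1). Exposure is a
user-supplied ordinal (1–4); PAR, chlorophyll-a and significant wave height
are consumed as pre-extracted site values. The site table joins environment,
thermal metrics, RA_POR and the population metric one row per site; missing
values are kept as explicit NaN markers and non-overlapping site keys are
reported, not silently dropped.

## Univariate and two-sample inference

Two-sample comparisons gate on Shapiro-Wilk at α = 0.05 per sample: both
normal → Welch's t (two-sided); otherwise a permutation test on the
difference in group means, exact by full enumeration when C(n₁+n₂, n₁) ≤
10⁵ (p = fraction of assignments at least as extreme; the observed
assignment is part of the enumeration, so no +1 correction), else Monte
Carlo with p = (1 + #{|d*| ≥ |d|})/(1 + B), B = 9,999 by default. Constant
samples fail the gate by convention; two identical constant samples give
p = 1.

The univariate screen fits an ordinary least-squares simple regression per
predictor and reports the signed correlation R, root-mean-squared residual,
slope, and raw p, with Bonferroni flags at α/m for α ∈ {0.01, 0.05, 0.10};
m defaults to the number of predictors screened (23 in the default
pipeline) and is recorded in the output metadata, since the appropriate
family size is a reporting choice rather than a property of the data.

## Additive models with shrinkage splines

Smooth terms use a natural cubic regression spline basis in the
values-at-knots parameterization, knots at quantiles of the (internally
standardized) covariate, with the integrated squared second derivative as
penalty. Basis dimension defaults to k = 3 per smooth — deliberately small
for site-level sample sizes (n ≈ 14–30). The penalty's null space (the
linear component) is eigen-modified to carry a weak penalty (0.1 × the
smallest positive eigenvalue), so a term shrinks smoothly through linear
toward zero as its smoothing parameter grows; the smoother can therefore
drop irrelevant covariates entirely. Each smooth is centered (sum-to-zero
constraint absorbed by reparameterization) and its penalty normalized to
unit Frobenius norm so smoothing parameters are comparable across terms.

Smoothing parameters are selected per term by generalized cross-validation,
GCV = n·RSS/(n − γ·edf)² with γ = 1.4, the standard inflation that guards
against GCV's tendency to undersmooth, via coordinate descent over a log
grid (10⁻⁷…10⁹, 49 points, 3 sweeps). Effective degrees of freedom are
diag((XᵀX + S_λ)⁻¹XᵀX). Reported statistics: deviance explained (1 −
RSS/TSS for the Gaussian family), adjusted r², GCV, and the second-order
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k = total edf + 1 (scale). The
Gaussian/identity family is used for BRI (bounded but far from both bounds
at the observed values); a thin-plate-style radial basis (|x−ξ|³ with ridge
penalty) is available as a sensitivity alternative, and GLM-style fits are
expressed as models with linear terms and centered pairwise product
interactions. Model comparison ranks by AICc and runs analysis-of-deviance
F-tests for declared nested pairs; a larger model that fails to reduce
deviance reports F = 0, p = 1 rather than an error.

A note on collinear predictors: when two predictors carry nearly the same
information (in these scenarios PAR and fDHW4 are both latitude-structured),
the shrinkage smoother legitimately zeroes one of them in a joint fit. The
sign of an individual effect is therefore established from its own
one-term model, the same way the univariate screen establishes signs.

## Community analysis

Bray-Curtis dissimilarity: Σ|x−y| / Σ(x+y) per site pair; all-zero rows are
an error. NMDS minimizes Kruskal stress-1 by alternating isotonic
regression of configuration distances on the rank-ordered dissimilarities
with Guttman majorization updates; the first start is the
principal-coordinates configuration, the remaining (default 19) are random
from the seeded generator; the best configuration is centered, rotated to
principal axes, and sign-fixed (non-negative coordinate sums) so output is
deterministic under a fixed seed.

PERMANOVA Gower-centers the squared-dissimilarity matrix (G = −½ J D² J)
and partitions tr(G) by sequentially added model terms via projection
matrices of the cumulative design: continuous covariates enter as centered
single-df regression columns, categorical factors dummy-coded with
df = levels − 1. Pseudo-F per term uses the full-model residual. p-values
come from unrestricted permutation of observation rows (no strata, matching
an unblocked design), exhaustively enumerated when n! ≤ the requested
permutation count (then p = #{F* ≥ F}/n!), else Monte Carlo with the +1
correction. Term order is the user's, defaulting to population → fDHW4 →
CV_SST → chl-a, and is recorded with the permutation count in the output
metadata. The implementation is cross-checked in the test suite against
exhaustive enumeration, against classical ANOVA on Euclidean distances, and
against `vegan::adonis2` through R.

## Sampling sufficiency

For each candidate image count n, the cover of all live coral and of the
top-k (default 4, determined from the full image set) most common live
taxa is recomputed over 1,000 random draws of n images without replacement
(with-replacement mode available); the coefficient of variation (sample
sd/mean) of those estimates forms the sufficiency curve, with null (not
infinite) CV for categories whose resampled mean is zero. At n = all
images every without-replacement draw is identical, so the CV is exactly 0.
`minimal_images` returns the smallest n at which all tracked categories
fall below a CV threshold (default 0.25), or a not-reached flag.

## Synthetic scenarios

The generator emulates the statistical structure of an equatorial atoll
chain under ENSO-modulated heat stress; it is a stand-in for field data,
not a climate or ecological model.

**SST.** Weekly series (1985–2012) = 29 °C mean + a 1 °C-amplitude seasonal
sinusoid (≈2 °C annual range, boreal-spring maximum) + an AR(1) interannual
component with 1-year autocorrelation 0.5 + white noise (sd 0.25 °C). The
interannual amplitude decays with latitude, γ(lat) = 4.0·exp(−|lat|/1.3) °C,
placing ≈1.4 °C at the most equatorial sites — year-to-year variability
about twice the seasonal sd, the defining regime — falling to ≈0.4 °C at
the northern atoll on the edge of the equatorial current's ENSO response.
Designated event years (2004, 2009) receive a raised-cosine boost (peak
2.5 °C over 16 weeks, centred mid-November); during event weeks the
seasonal component is held at its annual maximum, encoding that the warm
ENSO phase overrides the weak seasonal cycle — without this, a November
event could never clear the MMM-referenced HotSpot threshold.

**Bleaching.** Site latent severity η = 0.2 + 0.05·MaxDHW + 0.15·(PAR −
46) − 2.0·fDHW4, scaled per point by taxon susceptibility (1.0 for
*Acropora* down to 0.15 for *Porites rus*). A coral point's severity class
is an exponential draw with mean η·susceptibility binned at equally spaced
thresholds (step 0.35); η ≤ 0 scores every point normal. The defaults were
calibrated so the emulated cross-site structure matches the study
conditions the generator stands in for: site BRIs spanning ≈0.0–0.4 with
the northern (low-variability, high-light) atoll highest, and univariate
correlations of BRI ≈ +0.86 with PAR, ≈ −0.77 with fDHW4, ≈ −0.71 with
CV_SST. The small baseline (0.2) keeps the least-stressed sites at small
but nonzero BRI rather than an artificial floor at exactly 0.

**Communities and disturbance.** Per-atoll Dirichlet concentration vectors
give an *Acropora*-dominated northern atoll, a
*Heliopora*/massive-*Porites*/*Pocillopora* middle atoll, and a mixed
urbanized atoll. The urbanized sites draw large nearby villages, so their
population metric is ≈1.6–4 versus ≈0.02–0.07 elsewhere; the *Porites rus*
Dirichlet weight is multiplied by exp(1.2 × pop_metric) before
renormalization, producing *P. rus* dominance (≈50–95 % of live coral) at
disturbed sites — the weedy-coral pattern the community analysis is meant
to detect.

**What the generator does not emulate.** Physically realistic ENSO dynamics
(no teleconnections, skewness, or event clustering); acclimatization or
year-dependent bleaching response (both planted events have identical
response structure, so between-event BRI decline is out of reach); spatial
autocorrelation between neighboring quadrats; depth structure beyond a
single band per simulated survey; observation error in the satellite-style
covariates. Passing tests therefore demonstrate that the analysis chain
recovers planted effects of the stated sizes under clean sampling
assumptions — not that it would do so under field noise.

**Determinism.** Every draw flows from `default_rng([seed, site_index,
stage])` substreams, so any stage is bit-reproducible in isolation and the
whole scenario is bit-reproducible from one seed.

## Numerical choices and degenerate inputs

- Exact permutation p-values omit the +1 correction (the identity
  arrangement is enumerated); Monte Carlo p-values include it.
- Cover fractions and community-matrix rows sum to 1 within 1e-9; the
  sequential-SS partition closes within 1e-9 of the total.
- Welch/permutation gating treats constant samples as non-normal; two equal
  constant samples give p = 1.
- Zero-df factors, empty scopes, all-zero community rows, rank-deficient
  designs (reported with the offending terms), and baselines with too few
  complete years raise informative errors rather than returning numbers.
- NMDS non-convergence in all restarts flags the result instead of raising;
  stress comparisons across dissimilarity transforms are rank-based.
- Problem sizes in the test suite (series lengths ≈20–140 weeks for oracle
  checks, 14-site scenarios, 200-replicate power studies, 500-scenario null
  calibrations) were chosen to make simulation-based rates stable at their
  stated tolerances on a single CPU.

## Known limitations

- The Gaussian/identity family for BRI ignores the [0, 1] bounds; with site
  BRIs near 0 the model can fit slightly negative values. A beta or
  binomial-weighted family is not implemented.
- Per-term GCV on a grid is robust but not the fastest or most accurate
  smoothing selector (no REML); with k = 3 bases the practical difference
  is small.
- PERMANOVA offers no restricted permutation schemes or dispersion
  (PERMDISP) companion test, and the NMDS has no Shepard-diagram output.
- The pipeline treats site × depth rows as independent observations where
  both depths exist, as the default analyses do; no mixed-effects or
  spatial-correlation structure is available.
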