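# Methods

This note documents the models and procedures `fptrack` implements, the
choices made where the design was genuinely open, and what the synthetic
tests do and do not establish about real tracking data.

## Track preprocessing

Loggers in studies of this kind record at one to six fixes per minute;
analysis requires a common resolution. `regularise` thins each track to a
nominal interval (default 60 s) by greedy forward selection: keep the first
fix, then repeatedly the fix closest in time to `last_kept + interval`
within a half-interval window. No positional interpolation is performed —
interpolated positions would enter the first-passage geometry as fabricated
data. Recording gaps are preserved; retained-fix intervals exceeding twice
the nominal interval mark segment boundaries, across which first-passage
accumulation is never allowed.

Ground speed is attributed to the *incoming* segment of each fix, a
deterministic, order-independent convention. A fix reached below the sitting
threshold (default 10 km/h) is flagged as sitting on the water and excluded
from behavioural analysis; speeds over the retained sequence are recomputed
once, in a single pass. An iterated filter (re-flagging on recomputed
speeds until fixed point) was rejected: it couples distant fixes through
the removal order and can cascade through legitimate slow flight.
Consequently the guarantee is that every retained fix's *flagging* speed is
at or above the threshold; speeds recomputed across removed bouts may fall
below it (the bird genuinely sat there). Sitting removal does not create
segment boundaries: the bird's position is continuous through a sit, so
elapsed time across the bout legitimately accumulates into passage times.

Distances use the haversine formula on a sphere of radius 6,371,000 m.
Ellipsoidal geodesics were rejected as over-precise for per-minute seabird
fixes (< 1 part in 300 at these scales).

## First-passage time and the ARS scale

FPT at a fix is the backward plus forward time to cross a circle centred on
the fix. Crossing instants are interpolated linearly in distance-to-centre
along the segment between the last fix inside and the first outside — a
planar approximation that is accurate for radii up to ~1 km. A passage that
reaches the track end or a segment boundary while still inside the circle is
*missing*, not censored at the boundary; censoring would bias FPT downward
at track edges exactly where circles are large.

The radius sweep defaults to 40 log-spaced radii over 5–1,000 m (log
spacing resolves the small-scale end; count and range configurable). The
per-radius dispersion statistic is the variance of log FPT, the standard
formulation; because the log is monotone the argmax can differ from the
log-of-variance-of-raw-FPT alternative, which is available behind the
`variance_statistic` switch for sensitivity checks. Radii with fewer than 5
defined FPT values are not scored; a track whose profile is flat (e.g. pure
transit, variance < 1e-12 everywhere) has no detectable scale and is
omitted from the median with a warning. The working (global) ARS scale is
the median of per-track peak radii, with the even-count median as the mean
of the central pair.

## Behaviour classification

At the working scale, fixes with FPT above `t_high` (default 300 s) are
search. Within the low band (FPT ≤ `t_high`), fixes at or below the band
median are travel — "the lowest half" read as at-or-below-median, with ties
at the median all travel so the split is deterministic. The remainder is
excluded as behaviourally indeterminate. No lower FPT cut is applied: a
histogram's lower mode edge describes the data, it does not filter it.
`t_high` is a configuration constant; automatic valley detection in the FPT
histogram is deliberately not implemented — the threshold is a judgement
call that should be visible, not buried in a heuristic.

## Covariate rasters

Daily single-band rasters (SST °C, Kd(490) m⁻¹, chlorophyll-a mg m⁻³) are
prepared in the order: (1) block-mean aggregation to 0.05° (NA-ignoring, a
target cell missing only if it contains no valid source centre — this is
what fills cloud holes), (2) cellwise averaging of each tracking day with
the previous day (the animal's recent experience; one absent day falls back
to the other with a warning), (3) rank standardisation of the averaged
image onto [0, 20] (average ranks for ties, `20·(rank−1)/(N−1)`, missing
preserved). Averaging raw values before ranking is the default order; the
alternative (rank each day, average ranks) sits behind
`rank_after_average=False`. Ranks are continuous in [0, 20] rather than
integer bins, avoiding arbitrary bin-edge effects. The ranking window is
the configured analysis extent, not hard-coded to any particular study box.

Sampling is containing-cell with half-open `[west, east) × [south, north)`
cells — behaviour is related to the habitat pixel, so bilinear smoothing is
deliberately avoided. Rasters are stored as ESRI ASCII grids (`.asc`), a
plain-text single-band format carrying its own geotransform.

Two diagnostics mirror what a field analysis should report: the mean
pairwise Pearson correlation between a variable's daily images (temporal
predictability — near zero means the environment gives the birds nothing to
learn between days) and the pairwise correlations among the three ranked
covariates at modelled fixes (collinearity check).

## The habitat model

For fix *j* of bird *i*, with y = 1 for search and 0 for travel and x the
three covariate ranks,

    y_ij ~ Bernoulli(invlogit(x_ij' β + α_i)),   α_i ~ N(0, σ²).

The marginal likelihood integrates α out per bird; `fit_binomial_glmm`
maximises it with adaptive Gauss–Hermite quadrature: per group the
integrand is re-centred at its posterior mode (damped Newton) and scaled by
its curvature, so one node is the Laplace approximation and the default 25
nodes are effectively exact for this one-dimensional integral. The
optimiser is BFGS on (β, log σ); standard errors come from the inverse
observed information (central finite-difference Hessian at the optimum).
Wald Z and two-sided normal p-values per coefficient; no multiple-testing
adjustment. Covariates enter as raw 0–20 ranks without centring or scaling.
Random intercept only — no random slopes. A σ estimate below 1e-3 is
flagged as a boundary solution; non-convergence returns the fit flagged
rather than raising.

Goodness of fit uses latent-scale variance partitioning with the
logit-link distribution-specific variance π²/3:

    R²_marginal    = σ_f² / (σ_f² + σ² + π²/3),
    R²_conditional = (σ_f² + σ²) / (σ_f² + σ² + π²/3),

with σ_f² the population variance of the fitted linear predictor Xβ̂.
Population-level predicted probabilities (`predict_search_probability`) set
the random effect to zero and hold unnamed covariates at mid-rank 10, which
is how partial-effect curves are tabulated.

Wald intervals for the fixed effects condition on the estimated
random-intercept variance; with ~15 groups this leaves the intercept
interval slightly liberal (simulated coverage near 93–94% at nominal 95%),
while the covariate intervals are essentially nominal. The optimiser
finishes BFGS with a damped Newton polish on the exact quadrature
objective, so the reported solution has a vanishing score.

Observations entering the model are not thinned for serial autocorrelation
(consecutive fixes of one bird are a minute apart). This matches the
modelling frame the pipeline implements, but standard errors should be read
with that caveat; a user wanting conservative inference can thin the
behaviour table before `ModelData.from_frame`.

## Synthetic study conditions

The generator's defaults are the study conditions every stochastic test
runs under: 15 individuals, one to four trips each (uniform), trips of
8.7 h at 1 fix/min from a colony inside a ~2.5° ocean window; transit at
11 m/s with tightly concentrated headings (wrapped Cauchy, ρ = 0.95);
search at 5 m/s with uniform headings and per-minute exit probability 0.1;
speeds gamma-distributed (shape 16, CV 25%, keeping search flight reliably
above the 10 km/h sitting rule); sitting bouts starting at 0.02/min with
geometric mean duration 6 min at 0.3 m/s; a soft homing bias (weight 0.3)
toward the colony in each trip's second half, producing looping rather than
commuting geometry. The transit→search switch hazard is
`invlogit(β₀ + α_i + β·ranks)` evaluated on the same ranked two-day-averaged
aggregated rasters the analysis reconstructs; generating coefficients
default to β₀ = −2.247, β = (0.065, −0.050, −0.002) with σ_α = 1 — the
effect sizes the habitat model is expected to recover — so generator truth
and pipeline estimates are directly commensurable.

Rasters are spatially smoothed Gaussian noise (smoothing length 4 cells of
0.025°, ~11 km autocorrelation), mixed across days as an AR(1) with
ρ = 0.05 — a near-unpredictable environment — with a shared component
giving cross-variable correlation 0.2, 15% random cloud masking, and
physical scalings of SST ~ N(24.4, 3.2²) °C and log-normal Kd(490)
(median 0.03 m⁻¹) and chlorophyll-a (median 0.12 mg m⁻³).

The dedicated scale-recovery scenario (`SimConfig.ars_scenario`) raises the
switch hazard (β₀ = −0.6) and exit rate (0.25/min) so trips alternate
between transit legs and well-separated search patches of a few hundred
metres (realized bout extent ≈ 400–500 m across); under the fleet defaults,
search occupancy is high enough that log-FPT variance keeps growing toward
the kilometre scale and the per-track peak reflects bout spacing as much as
bout size — a property of the scale estimator worth knowing about when
reading real profiles.

What the generator does *not* emulate: GPS positional error, wind and
current drift, prey fields or memory, behaviour-dependent sitting, land
masking, and raster gradients tied to bathymetry. Passing tests therefore
establish the correctness of the computations and the recoverability of
effects under the assumed model structure — not robustness of the method to
violations of that structure in field data.

## Numerical choices and degenerate inputs

- FPT exit search uses the running maximum of distance-to-centre, so the
  first fix outside radius r is found by one sorted lookup per radius; the
  result is identical (to < 1e-6 s) to an O(n) fix-by-fix walk, which the
  tests enforce.
- The even-count median convention (mean of central pair) applies to the
  ARS scale; ties at the classification median all become travel.
- Constant (degenerate) raster images rank to 10 everywhere with a warning;
  correlation diagnostics skip constant images/pairs with fewer than 3
  jointly valid cells.
- A track shorter than one nominal interval is flagged unusable; a trip
  whose profile cannot be scored raises a scale-undetectable error that the
  pipeline converts to an omission with a warning, failing only when no
  track survives.
- All simulation randomness flows from one integer seed through one
  `numpy` generator; the analysis stages are deterministic given data.

## Problem sizes in the validation suite

The stochastic tests run at the study scale where that is cheap (full
8.7-h trips for scale recovery and sitting concordance; 15 × 450
observations and 200 replicates for interval coverage; 50 replicates of the
complete pipeline for sign recovery) and at reduced fleet sizes for smoke
and concordance checks (3–5 birds), sizes chosen to keep the suite fast
while leaving each property's power essentially unchanged.
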