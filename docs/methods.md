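# Methods

This note records the models the package implements, the assumptions and
numerical devices behind them, what the synthetic-data layer does and does
not emulate, and the design choices made where more than one defensible
option existed.

## Landscape covariates

Rasters are regular square grids in projected meters, row-major from the
top-left corner, sampled at cell centers; I/O is ESRI ASCII (text) or
single-band float32 GeoTIFF with explicit nodata.  The covariates are:

| name | seasonal | meaning | construction |
|---|---|---|---|
| cover | no | % shrub/forest within a 50 m radius | closed-disc neighborhood over a binary classification |
| tri | no | terrain ruggedness | √Σ(z_neighbor − z_cell)² over the 8 neighbors; edges use in-bounds neighbors only |
| evi | yes | vegetation greenness (forage proxy) | supplied/simulated per season |
| dist_river | no | distance (m) to the nearest river course | point-to-polyline distance |
| dist_human | yes | distance (m) to the nearest boma | nearest-neighbor distance to the seasonal boma set |
| dens_human | yes | boma count within a 1/3/5 km radius | closed-disc count; the radius is chosen by AIC |

Neighborhoods are closed discs (boundary points included) — a deterministic,
testable convention.  All covariates are centered and scaled before
modelling, each seasonal layer with its own constants, and the constants are
stored on the stack so raw values can be recovered.  A distance-to-water
layer is generated (water points drive dry-season herding) but excluded
from the default model formulas; it is retained so its correlation with
distance-to-human can be inspected.

## The synthetic landscape and tracks

`generate_synthetic_landscape` builds smooth correlated Gaussian fields
(cover via a logistic transform, mean ≈ 30%; EVI with the wet layer greener
than the dry on average; a DEM whose ruggedness rises eastward), a
meandering river polyline, and a Thomas-process (clustered) boma pattern.
A western "shortgrass plains" polygon is vacated by a configurable fraction
of its bomas (default 0.85) in the wet season, reproducing the seasonal
shift in human pressure that motivates separate wet/dry human layers.

`simulate_ssf_track` generates movement from a known step-selection model:
step lengths gamma (default shape 2, scale 300 m, floored at 1 m to avoid
degenerate turn angles), turn angles von Mises relative to the previous
heading (uniform at the first step), selection weight exp(βᵀx) on the
scaled covariates at the candidate endpoint, seasonal layers switching by
calendar month (wet = Dec–May, dry = Jun–Nov).  Steps are drawn **exactly**
from the target density kernel(s)·exp(βᵀx) by rejection sampling against a
per-season upper bound on the linear predictor.  A softmax-over-candidates
mode is retained (`method="softmax"`); it is approximate, and with only a
few hundred candidates it measurably attenuates slopes recovered from long
tracks, because the chain concentrates where exp(βᵀx) varies steeply.
Candidates leaving the extent are redrawn, so the movement kernel is
truncated to the landscape — the availability sampler applies the same
truncation.

What the generator does **not** emulate: GPS fix loss and location error,
behavioral modes (resting vs. traveling), social constraints (territories,
prides), prey fields, and temporal covariate dynamics beyond the two-season
switch.  Passing recovery tests therefore shows that the estimators are
correct for the model they assume, not that the model captures every
feature of real collar data.

## Trajectory preparation

* **Resampling** to ~12 h (landscape scale): keep the first fix, then
  repeatedly the fix closest to one interval after the last kept fix among
  those within ±tolerance (default 120 min); across gaps, resume at the
  next available fix.  Idempotent by construction.
* **Steps** (local scale): consecutive fixes at the target interval
  (default 1 h ± 30 min) become used steps; bursts break at gaps; the turn
  angle is the signed heading change in (−π, π], with exact reversals
  mapped to +π.
* **Season** is assigned by calendar month (Dec–May wet, Jun–Nov dry);
  **diel** by the sign of the solar elevation at the fix time and location
  against the refraction-corrected −0.833° horizon, computed with the NOAA
  solar-position equations.  Projected coordinates are converted to lon/lat
  with a local equirectangular approximation about a reference point —
  adequate for solar geometry over tens of kilometers, not a CRS transform.
* **Movement kernels**: gamma by maximum likelihood on step lengths, von
  Mises by closed-form mean direction plus Newton inversion of the Bessel
  ratio for κ, capped at 700 with a degeneracy flag.
* **MSD** is the mean squared distance (km²) from the animal's first fix in
  the period under analysis.  Because the magnitudes are often quoted in
  linear units, the square root is reported alongside.  The seasonal
  contrast uses a Gamma GLM with log link (positive continuous response) on
  the per animal-season MSD table, dry season as reference; a degenerate
  zero-variance table is handled in closed form.

## Estimation

Both used/available designs are fitted by penalized Newton iterations on
the joint fixed-effect/random-effect objective, with random effects
integrated by the Laplace approximation.

**RSF.**  Weighted Bernoulli likelihood: used rows weight 1, available rows
weight 1000 (the "infinitely weighted" logistic device, making the fit
approximate the inhomogeneous point-process likelihood).  Per-animal random
intercepts have their variance *fixed* at 10³ (not estimated, not counted
in AIC's k); random slopes, when enabled, are diagonal with variances
maximized on the Laplace marginal (Nelder–Mead on log-variances).  The
global intercept is reported but depends on the availability ratio and is
not interpreted.  Doubling the available weight moves slopes by well under
1%, as the device requires.

**SSF.**  The Poisson formulation: one intercept per stratum treated as a
Gaussian random effect of fixed variance, which conditions the strata out
while allowing additional random structure.  Stratum intercepts are
profiled through a Schur complement, so each Newton iteration is linear in
the number of rows; standard errors come from the inverse Schur complement
of the dense block.  The exact conditional-logistic Newton maximizer (the
likelihood conditional on one used point per stratum) serves as an
independent oracle: on 200 simulated strata the two agree to |Δβ| ≈ 4·10⁻³.

*On the fixed variance.*  10³ is the conventional choice and the package
default.  The device's agreement with the exact conditional likelihood
degrades when the between-stratum spread of covariate means is large
relative to the variance: on synthetic tracks of 2,500 strata over a patchy
landscape, σ² = 10³ shrank the cover slope from 0.775 (exact) to 0.703,
while σ² = 10⁵ reproduced the exact estimate to four decimals.  The
validation experiments therefore fit with σ² = 10⁵, so they measure the
estimator rather than the device's conditioning slack; users fitting data
with strong spatial structure should check sensitivity to this setting.

*On availability kernels.*  Sampling available steps from a kernel
*re-fitted* to the observed (selection-tilted) steps — the common empirical
protocol — adds a small attenuation relative to sampling from the true
kernel (the classic tentative-kernel issue; correctable by step-length and
turn-angle adjustment covariates, available behind a flag but off by
default).  The recovery experiments sample availability from the generative
kernel to isolate the selection estimator.  A further small attenuation of
slopes on very smooth covariates (≈ −0.04 for distance-to-human) appears
only on long chains, whose stationary distribution parks animals at local
covariate extrema; many short tracks show no measurable bias.

**Model and radius selection.**  AIC = 2k − 2·loglik with k = fixed effects
plus freely estimated variance components (fixed-variance terms excluded);
the log-likelihood is the Laplace marginal.  Ties break toward fewer
parameters (and the smaller radius in the 1/3/5 km comparison);
non-converged fits are excluded with a warning.  The six candidate SSF
formulations are: all predictors; all predictors plus cover×dist_human and
cover×dens_human; habitat only; human only; cover only; habitat without
cover.

## Used-habitat calibration

Strata (not rows) are split 50/50 at random.  The model is fitted on the
training half; 1,000 slope vectors are drawn from N(β̂, V̂); per draw, one
"predicted used" point is sampled from each test stratum's available points
with weight exp(β*ᵀx) (Gumbel-max trick), matching the conditional
structure of the likelihood and the observed one-used-per-stratum count.
Covariate values are smoothed with a Gaussian kernel — bandwidth from
Scott's rule on the pooled test values, held identical across observed and
simulated densities — onto a 512-point grid spanning the availability
range.  The envelope is the pointwise 2.5/97.5 percentile band; a panel's
`coverage_fraction` is the fraction of grid points whose observed density
lies inside it.  Panels can be requested for covariates *omitted* from the
model — that is how a missing predictor is detected (in the validation
battery the omitted-cover panel drops to ≈ 0.5 while included covariates
average ≥ 0.94).  Two design points matter when testing calibration.
First, single-split coverage is a noisy statistic (one training fit;
correlated grid points), so the calibration experiment averages panels over
three independently simulated datasets.  Second, the calibration experiment
generates *independent* single-step strata: along a real track, consecutive
used endpoints are serially autocorrelated (each endpoint is the next
step's start), which inflates the sampling variance of the observed
used-habitat density beyond what the envelope's independent per-stratum
resampling expresses — on serially dependent tracks even a well-calibrated
envelope will under-cover somewhat (we measure ≈ 0.88–0.92 instead of
≈ 0.95), which is worth remembering when reading these plots for real
telemetry.

## RSS and resistance

For each covariate in the top model, RSS(Δh) = exp(β·Δh) is evaluated on
200 equally spaced values of the covariate's scaled range, with Δh measured
from the scaled landscape mean (0) and interaction partners held at their
scaled means.  A least-squares line (α₀, α_x) through the curve is stored.
Per-cell resistance sums 1 − RSS over covariates; the default uses the
linear approximation, `R = Σ_c [1 − (α₀ + α_x X_c)]`, and an exact mode
`R = Σ_c [1 − exp(β_c X_c)]` is provided.  The two agree as the covariate
range shrinks (the gap falls ~quadratically with the range), but the
least-squares line has a constant offset at X = 0 when fitted over a wide
range — a property of the linear reading, visible in the identity checks.
Negative resistance means net attraction; the display transform is the
signed log `sign(R)·log(1+|R|)` (odd, monotone, order-preserving).
Resistance is mapped per season from a single coefficient set (no diel
stratification), by default the category of wide-ranging males that drives
connectivity.

## Numerical conventions

Convergence: relative change of the penalized objective below 10⁻¹⁰ with
step-halving line search, at most 200 iterations; ‖β‖ > 30 flags suspected
separation and marks the fit non-converged.  Design matrices are checked
for full rank, and SSF covariates for within-stratum information (a
covariate constant inside every stratum is an error).  All random
operations take explicit integer seeds; identical seeds give bit-identical
outputs, including GeoTIFF/ASCII round trips up to float formatting.

## Problem sizes in the validation battery

The experiments run on a 20×20 km landscape at 200 m resolution: oracle
equivalence on 200 strata; SSF recovery on 20 replicates of 5 animals × 500
steps (50 available steps per stratum); RSF recovery on 20 replicates of
2,000 used points at 100:1 availability; UHC on 3 replicate datasets of
2,000 independent single-step strata at 1,000 draws; radius identification
on 20 replicates
of 3 animals × 400 steps; MSD behavior on 50 replicate walks and 50
replicate seasonal tables.  The whole battery completes in about six
minutes on one CPU.

## Known limitations

* Random-slope covariances are diagonal; slope-slope correlations are not
  estimated.
* Wald intervals throughout; no profile likelihood or bootstrap.
* The weighted-logistic RSF and the fixed-variance Poisson SSF are
  approximations whose quality depends on the weight and variance settings;
  both are checked against independent references here, but on real data
  the sensitivity checks (doubling the weight, raising the fixed variance)
  are worth repeating.
* The resistance map stops at per-cell resistance; no circuit-theory or
  least-cost connectivity metrics are computed.
* Day/night classification assumes the local equirectangular lon/lat
  approximation; tracks spanning hundreds of kilometers would need a true
  CRS transform.
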