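# lionhab

Multi-scale habitat selection and movement analysis for GPS-collared African
lions (*Panthera leo*) in a rangeland shared with pastoralists.

Lions persisting in multi-use landscapes balance the benefits of good
habitat — vegetation cover for shelter and stalking, rugged terrain, green
forage that concentrates prey, riverbeds — against the risk posed by human
activity, proxied by mapped pastoralist homesteads ("bomas") whose
distribution shifts between wet and dry seasons.  This package implements
the full analysis chain used to quantify those trade-offs from collar data,
and, because collar datasets of this kind are rarely public, ships a
synthetic-data layer (raster landscape generator and step-selection track
simulator with known coefficients) so every estimator can be validated by
parameter recovery.

## What it computes

* **Landscape scale — resource-selection function (RSF).**  Used locations
  (thinned to 12-h spacing, clipped to the study area) versus 100 uniform
  available locations per used fix, fitted as a weighted logistic
  regression, `logit P(used) = β₀ + βᵀx`, with available rows weighted 1000
  so the fit approximates the point-process likelihood, a per-animal random
  intercept with variance fixed at 10³, and optional per-animal random
  slopes.
* **Local scale — step-selection function (SSF).**  Each observed step is
  matched with 50 available steps drawn from the animal's fitted movement
  kernel (gamma step lengths, von Mises turn angles); slopes are estimated
  through the Poisson formulation of conditional logistic regression
  (stratum intercepts as random effects with variance fixed at 10³).  An
  exact conditional-likelihood Newton maximizer,
  `L(β) = Πₛ exp(βᵀx_used,s) / Σⱼ exp(βᵀx_j,s)`, is provided as an
  independent oracle.  Six candidate formulations (all predictors, with
  cover×human interactions, habitat-only, human-only, cover-only,
  habitat-without-cover) are ranked by AIC, as is the radius (1/3/5 km)
  for the boma-density covariate.
* **Validation — used-habitat calibration (UHC).**  Stratum-level
  train/test split; 1000 slope vectors drawn from N(β̂, V̂); per draw,
  predicted used points are resampled within each test stratum with weight
  exp(β*ᵀx) and smoothed into a density; the pointwise 95% band is compared
  with the observed test-used density.
* **Movement — mean squared displacement (MSD).**  Per animal-season MSD
  (km², plus its square root), and a Gamma GLM with log link contrasting
  wet versus dry season (dry as reference).
* **Mapping — relative selection strength (RSS) and resistance.**
  RSS(Δh) = exp(β·Δh) on a 200-point grid per covariate; per-cell
  resistance `R = Σ_c [1 − (α₀ + α_x X_c)]` (linear-fit mode; an exact
  exponential mode is available), with a signed-log display transform.

## Worked example

```python
import lionhab as lh
import lionhab.trajectory as tj
import lionhab.ssf as ssf

# a 20 x 20 km synthetic rangeland at 200 m resolution
raw, points, area, plains = lh.generate_synthetic_landscape(seed=2, extent=(20e3, 20e3), cell_size=200.0)
stack = lh.scale_covariates(raw)

# simulate one lion that seeks cover and keeps its distance from bomas
kernel = lh.MovementKernel(gamma_shape=2.0, gamma_scale=300.0, vm_mu=0.0, vm_kappa=0.5)
coeffs = lh.SelectionCoefficients(beta={"cover": 0.8, "dist_human": 0.5})
track = lh.simulate_ssf_track(stack, kernel, coeffs, (10e3, 10e3), n_steps=500, seed=3)

# rebuild steps, match 50 available steps per stratum, fit the SSF
steps = tj.build_steps(track, step_interval_hours=1.0)
data = ssf.sample_available_steps(steps, kernel, stack, k=50, seed=5)
fit = ssf.fit_ssf_poisson(data, ["cover", "dist_human"])
print(fit.summary_frame())
```

```
         term  estimate        se         z     ci_lo     ci_hi
0       cover  0.824546  0.167573  4.920513  0.496109  1.152984
1  dist_human  0.522159  0.175035  2.983167  0.179097  0.865222
```

Both 95% confidence intervals cover the generative truth (0.8 and 0.5): a
single 500-step track already pins down the cover preference well, while
the smoother distance-to-human field is estimated with more uncertainty.

The numbered scripts under `analysis/` run the full study pipeline on the
synthetic landscape — landscape build, tracks and MSD, density-radius
selection, six-model SSF competition with season × diel refits, seasonal
RSFs, UHC validation, and resistance mapping — each printing what it found
and writing tables under `results/analysis/`.  `lionhab run-all` does the
same through the CLI from a YAML config.

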