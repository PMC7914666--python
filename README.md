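# orchardssc

Non-destructive monitoring of soluble solids content (SSC, % ≈ °Brix) in
orchard fruit: partial least squares calibration of SSC from Vis/NIR point
spectra, Monte Carlo evaluation of the calibration design, and longitudinal
linear mixed-effect models of SSC accumulation under orchard treatments.

The package is aimed at horticultural scientists and chemometricians who
want to (a) calibrate a handheld spectrometer against refractometer reference
values, (b) decide how many laboratory reference samples a season really
needs and how sensitive the calibration is to laboratory error, year-to-year
transfer and the covered SSC range, and (c) model weekly SSC trajectories of
individual fruit with tree- and fruit-level random effects. Because orchard
field campaigns are rarely public, the package ships first-class synthetic
generators with known ground truth for both the spectral and the
longitudinal stages, so every method can be validated by parameter recovery.

## Methods at a glance

**Calibration.** Raw absorbance scans on a 3 nm grid (310–1100 nm window)
are transformed to Savitzky–Golay second derivatives (window 9 points,
polynomial order 2) and restricted to 729–975 nm. A univariate partial
least squares regression (NIPALS/PLS1, predictor-block deflation) with at
most 7 latent components is fitted; the component count minimises the
leave-one-out cross-validation RMSE. Validation reports RMSEP,
adjusted R² = 1 − (1 − R²)(n − 1)/(n − a − 1) with a latent components, and
the slope/intercept of the modelled-vs-laboratory bias line.

**Monte Carlo design sensitivity.** Repeated stratified resampling
(per year, SSC-quartile balanced) of calibration sets maps the mean ± sd
RMSEP against calibration size per year (20 … 500), added laboratory error
(N(0, s²), s = 0 … 2.0 % SSC, calibration responses only), validation SSC
bins (<9 … >13 % SSC), train-year × validate-year transfer, and scan
temperature (10/20/30 °C).

**Longitudinal models.** For observation k of fruit i on tree j,

    y_ijk = β0 + u_j0 + u_i0 + (β1 + u_j1 + u_i1) t_k
            + β_X X_i + β_Y X_i t_k + e_ijk

with t in weeks after full bloom (WAFB; DAFB = 7·WAFB), treatment dummies X
(year, canopy sector, crop load, cell-division temperature, calcium) coded
against their baselines, and independent Gaussian random intercepts/slopes
for trees and for fruit nested in trees. Model 1 is the full specification,
Model 2 drops the time interactions (β_Y = 0), Model 3 drops the random
effects (OLS baseline). REML provides estimates and variance components, a
parallel ML fit the AIC/BIC; coefficients with |t| > 2 are flagged
significant. Expected-effect tables by DAFB and design-sensitivity refits
(fewer trees, fewer fruit, added response noise) are provided, as is a
Mann–Whitney–Wilcoxon comparison of destructive vs spectral SSC at harvest.

## Worked example

```python
from orchardssc.config import SpectraConfig, OrchardConfig
from orchardssc.synthetic import generate_spectra, generate_orchard, spectra_matrix
from orchardssc.preprocess import second_derivative
from orchardssc.plsr import fit_plsr, predict, prediction_stats
from orchardssc.lme import fit_lme, evaluate_effects

spectra = generate_spectra(SpectraConfig(n_samples=2400, seed=1))
deriv = second_derivative(spectra)                  # d2 absorbance, 729-975 nm
wl, X = spectra_matrix(deriv)
y = deriv["ssc_ref"].to_numpy()
model = fit_plsr(X[:1500], y[:1500], wavelengths=wl)
stats = prediction_stats(predict(model, X[1500:]), y[1500:], model.n_components)
print(f"components={model.n_components}  RMSEP={stats.rmsep:.2f} % SSC  "
      f"adj R2={stats.adjusted_r2:.2f}  bias slope={stats.bias_slope:.2f}")

orchard = generate_orchard(OrchardConfig(seed=1))   # 237 trees, 1274 fruit
fit = fit_lme(1, orchard, information_criteria="same")
print(f"week slope = {fit.estimates['week']:.3f} % SSC/week, "
      f"top sector = {fit.estimates['sector:top']:.2f} % SSC")
print(evaluate_effects(fit).head(3).to_string(index=False))
```

prints

```
components=7  RMSEP=0.68 % SSC  adj R2=0.93  bias slope=1.00
week slope = 0.303 % SSC/week, top sector = 0.37 % SSC
 dafb  base  sector:middle  sector:top  crop_load:light  crop_load:heavy  temperature_trt:cold  temperature_trt:warm
 40.0  5.43           0.20        0.51             0.04            -0.02                  0.14                  0.16
 60.0  6.29           0.25        0.58             0.10            -0.03                  0.11                  0.13
 80.0  7.16           0.30        0.65             0.16            -0.04                  0.08                  0.10
```

The calibration selects 7 latent components and predicts held-out SSC to
0.68 % SSC with no systematic bias (slope 1.00). The mixed model recovers
the generating weekly accumulation (0.31 % SSC/week) and top-sector effect
(0.39 % SSC) within their sampling error; the effect table shows the
expected SSC of the baseline configuration by days after full bloom and the
additive offsets of each treatment level.

The same stages are available from the shell: `orchardssc generate`,
`preprocess`, `calibrate`, `montecarlo`, `lme`, `effects`,
`compare-harvest`, and `full-run` (which chains everything and writes a
manifest with seeds and artifact checksums).

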