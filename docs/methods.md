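# Methods

This note documents the models implemented in `orchardssc`, the synthetic
data they are validated against, the defaults and why they were chosen, and
the numerical decisions that matter when reproducing results.

## Spectral forward model (synthetic generator)

A scan with soluble solids content `ssc` (% SSC) at fruit temperature `T`
(°C) is generated on a uniform wavelength grid as

    A(λ) = baseline(λ)
         + ssc · Σ_b gain_b · exp(−(λ − c_b − s·(T − 20))² / (2 w_b²))
         + ε(λ),      ε ~ N(0, σ_A²) iid per channel.

* **Grid** — 3 nm sampling inside a 310–1100 nm instrument window. Channels
  sit on integer multiples of the step, so the 729 and 975 nm bounds of the
  modelling window are grid points (312, 315, …, 1098 at defaults; 83
  channels inside the window).
* **Bands** — two Gaussian absorption bands at 840 and 960 nm, widths 25 nm,
  gains 0.004 and 0.003 AU per % SSC. Carbohydrate and water features of
  fruit tissue lie in this region; two overlapping bands make the PLSR
  problem non-trivial (no single channel is sufficient).
* **Temperature** — scans are taken at 10/20/30 °C; band centers shift by
  0.15 nm/°C around the 20 °C reference, mimicking hydrogen-bonding shifts.
  A multi-temperature calibration set therefore has to span the shifted
  signatures, as a field calibration must.
* **Reference SSC** — uniform over 5–14 % SSC, the range covered by a full
  season from early development to harvest maturity.
* **Noise** — σ_A = 0.0055 AU. This is the one generator scale that was
  calibrated (once) rather than assumed: it makes a 7-component PLSR
  calibrated on 500 scans/year predict held-out SSC with RMSEP ≈ 0.67 % SSC,
  the reported accuracy level of field calibrations of this type, so the
  Monte Carlo results live on a realistic error scale.

The baseline (gentle linear trend plus a broad visible-range bump) carries
no SSC information and is identical across scans; second-derivative
preprocessing removes it almost entirely.

What this generator does **not** emulate: light scattering and path-length
variation between fruit, multiplicative effects (hence no SNV/MSC step),
daylight background (removed in-device on real instruments), instrument
drift between seasons, and non-uniform SSC distributions over time. Passing
tests therefore demonstrate correctness of the estimation machinery and the
qualitative design laws, not field accuracy of any particular instrument.
Synthetic years are exchangeable by construction, so year-transfer analyses
on default synthetic data measure the *absence* of transfer loss; real
year-to-year transfer loss needs year-specific structure (e.g. different
`band_gains` per year).

## Preprocessing

Second derivatives are computed with a Savitzky–Golay smoothing derivative,
default window 9 points (27 nm) and polynomial order 2, then cropped to the
inclusive 729–975 nm window without interpolation. The derivative method and
its parameters are config-exposed because published work in this area rarely
states them; order-2 exactness (a quadratic spectrum returns exactly its
second derivative) and linearity are unit-tested.

## PLSR

PLS1 (univariate response) with NIPALS-style extraction and deflation of the
predictor block only; the response loading is recomputed per component. With
a single response the weight vector per component is closed-form (w ∝ X'y),
so no inner iteration is required. Predictions use the equivalent linear
coefficient vector b = W(P'W)⁻¹q around the training means.

* **Component selection** — global minimum of leave-one-out CV RMSE over
  1…7 candidates, ties toward fewer components; a one-standard-error rule is
  available (`select="one_se"`).
* **LOO implementation** — each fold is obtained by rank-one downdates of
  the Gram matrix X'X and of X'y (with exact re-centering), and components
  are extracted in Gram space at O(p²) per fold independent of n. This is
  algebraically identical to the X-space extraction (unit-tested to 1e−8)
  and keeps 1500-sample LOO inside a second.
* **Degenerate responses** — a constant y yields a flagged model predicting
  the training mean.
* **Oracle status** — with as many components as the predictor rank, PLS1
  predictions equal ordinary least squares; scikit-learn's PLSRegression is
  used in the test suite as an independent cross-check, never as the
  implementation.

Validation statistics: RMSEP, adjusted R² (using the number of latent
components as the predictor count), and an OLS bias line of laboratory
values on predictions.

## Monte Carlo calibration-design analysis

Each scenario repeats, for `reps` replicates: draw a stratified validation
set (default sizes per mode mirror the corresponding published analyses:
200/year for sample-size scans, 100/year for laboratory-error and transfer
scans), draw a disjoint stratified calibration set, optionally perturb the
calibration responses with N(0, s²) laboratory noise (validation responses
are never touched — instrumented in tests), fit the PLSR calibration, and
record the validation RMSEP. Stratification is by year always and by
within-year SSC quartiles by default, so small calibration sets still cover
the response range. Per-replicate seeds spawn from the master seed
(`numpy.random.SeedSequence`), making every replicate independently
reproducible.

The default replicate count is 500; source material for this kind of
analysis states both 100 and 500 for different sections, so the count is a
config parameter rather than a constant. The acceptance checks use 50
replicates per setting, which is enough to resolve the qualitative laws
(monotone RMSEP in calibration size; < 1.3× RMSEP inflation under 2 % SSC
laboratory noise at 500 scans/year; transfer symmetry for exchangeable
years) on one CPU in a few minutes.

## Longitudinal mixed-effect models

The weekly SSC trajectory of fruit i on tree j is

    y_ijk = β0 + u_j0 + u_i0 + (β1 + u_j1 + u_i1)·t_k + β_X X_i + β_Y X_i t_k + e_ijk

with independent univariate Gaussian random effects (no intercept–slope
correlation parameters — the generating specification defines separate
normals, so correlations are deliberately excluded) and t in WAFB. Day-based
interfaces convert via DAFB = 7·WAFB. Baselines: year 2016, bottom sector,
standard crop load, ambient cell-division temperature, calcium applied.

* **Estimation** — statsmodels `MixedLM` with tree as the grouping factor, a
  free random intercept, and variance components for the tree slope and the
  nested fruit intercepts/slopes. REML is the default for reported
  estimates; AIC/BIC come from a parallel ML fit (so fixed-effect structures
  are comparable), computed as −2ℓ + pen·k with k = fixed effects + variance
  parameters (+ residual).
* **Optimisation** — a fast L-BFGS pass followed by a BFGS refinement from
  its endpoint. L-BFGS occasionally reports convergence at a non-optimal
  point of the profiled deviance; the refinement either confirms the optimum
  cheaply or escapes it, and from-scratch BFGS/Powell restarts are the
  fallback. Near-zero variance estimates are flagged `singular`, not
  rejected.
* **RMSE** — over conditional residuals (BLUPs subtracted).
* **Significance** — |t| > 2, strictly; Satterthwaite p-values are out of
  scope by design.
* **Effect tables** — expected SSC of the baseline configuration and
  per-level offsets, each affine in time: base = β0 + β1 t, offset =
  β_X + β_Y t, reported to 0.01 % SSC at DAFB 40…140. The same table can be
  built from published anchor values at two DAFB points
  (`coefficients_from_anchors`), since two points determine each affine
  trajectory. Tables from a pooled multi-year fit can be evaluated at a
  specific year level via the `year` argument; evaluating a single-year
  refit is the alternative route when year-specific slopes matter.
* **Design sensitivity** — refits of Model 1 on 100 random trees, on 500
  random fruit, and on the full data with N(0, 1) response noise,
  reproducibly seeded; reduced designs inflate coefficient SEs and added
  noise adds ≈ 1.0 to the residual variance (both tested).

### Orchard generator defaults

The default design spans three seasons (33 trees/198 fruit, 96/603,
108/473 — 237 trees and 1274 fruit in total, the documented design scale of
multi-season orchard trials of this kind), with 14 weekly visits at WAFB
8–21 and treatments as a randomised full cross over trees, sectors cycling
within tree. Fixed effects default to the multi-year coefficient set
(intercept 3.78, week 0.31, year offsets 1.47/1.85, sector 0.11/0.39, crop
load −0.07/−0.03, temperature 0.15/0.21, calcium 0.17 % SSC); time
interactions default to the per-week slopes implied by published early/late
effect values (e.g. top sector +0.0252 % SSC per week). Variance components
default to σ_tree,0 = σ_fruit,0 = 0.3, σ_tree,1 = σ_fruit,1 = 0.02,
σ_e = 0.3 % SSC. With these defaults the conditional RMSE of Model 1 is
≈ 0.25 % SSC and the marginal (fixed-effects-only) RMSE ≈ 0.53 % SSC; the
0.48 % SSC scale reported for comparable field fits lies between the two.
An optional per-week dropout probability (default 0, fruit once lost stay
lost) exercises unbalanced data.

The generator emits one scan per sample; duplicated scans of the same fruit
(two sides) are available behind `duplicate_scans`, but no aggregation
policy is asserted — averaging vs keeping both is left to the caller.

## Harvest comparison

Destructive laboratory values are emulated as pooled batches (mean of 8
fruit plus blender noise), non-destructive values as individual
PLSR-modelled fruit with a larger spread. The agreement summary reports
per-method means/sds, per-treatment-level differences (both the mean of
absolute differences — the headline number — and the signed mean as a bias
check; levels observed under a single method are excluded and counted), and
a two-sided Mann–Whitney–Wilcoxon test: exact null distribution for samples
of at most 20 without ties, normal approximation with midrank-tie and
continuity corrections otherwise (the rank test is used because modelled SSC
values are generally not normal). Exactness is verified against exhaustive
permutation enumeration for all splits with group sizes up to 5.

## Problem sizes and runtime

Default test and acceptance runs use: 2400 synthetic scans (800/year) as the
Monte Carlo reference pool; 50 Monte Carlo replicates per setting; 20
replicates at the full 237-tree design for fixed-effect recovery; 20
replicates at a 36-tree/300-fruit design for the AIC ordering of the nested
models (large enough that the weekly interaction effects of ~0.01–0.03
% SSC/week are resolved against the random-slope spread). These sizes were
chosen so the complete suite runs on a single CPU in minutes while keeping
every stochastic check well away from its decision boundary.

## Known limitations

* The spectral generator is a two-band linear absorbance model — no
  scattering, no multiplicative effects, no drift; conclusions about
  absolute field accuracy do not follow from it.
* Synthetic years are exchangeable, so the transfer analysis demonstrates
  symmetry rather than realistic between-year degradation.
* Random-effect correlations (intercept–slope) are intentionally not
  modelled.
* The Mann–Whitney exact path requires tie-free samples; tied small samples
  fall back to the corrected normal approximation.
* AIC/BIC parameter counting includes variance parameters without boundary
  corrections; near-boundary fits are flagged but their criteria are
  reported as-is.
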