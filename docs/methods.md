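# Methods

This note records the models, conventions and design choices behind
`specfuse`, at the level a maintainer or reviewer needs to judge what the
package computes and what its tests do and do not demonstrate.

## The problem

A VIS/NIR calibration maps a reflectance spectrum r(λ) to an analyte value
(here soluble solids content, SSC, in %).  Calibrations are built under one
measurement condition; when the condition changes (cultivation mode, batch,
season), band positions and baselines drift and the model's predictions
degrade far beyond its nominal error.  The package implements a model-update
strategy with two ingredients: merging the characteristic wavelengths of
both conditions while removing position-shifted repeats, and augmenting the
calibration set with a small, optimally chosen number of new-condition
samples.

## Synthetic data generator

No public spectra exist for the motivating study, so the generator stands
in for the instrument.  A clean spectrum is

r(λ) = b₀ + b₁·(λ−λ₀)/(λ₁−λ₀) − Σ_k (d_k + s_k·SSC)·exp(−(λ−c_k−δ)²/(2w_k²)) + ε

with ε ~ N(0, σ_noise²) i.i.d. per channel.  Defaults: grid 350–2500 nm at
1 nm; baseline b₀ = 0.75, b₁ = −0.05 (reflectance units); four Gaussian
bands at c_k = 970, 1190, 1450, 1940 nm (widths 40–70 nm, base depths
0.08–0.25, SSC slopes 0.003–0.005 per %SSC) — the O–H/C–H water and sugar
features that drive SSC calibration in fruit; σ_noise = 0.005, a typical
reflectance noise floor for a field spectrometer.  SSC is drawn from a
truncated normal by rejection sampling, with the two conditions'
mean/SD/min/max set to the reported statistics of the two cultivation
modes (open field: 26.59 ± 2.78 in [21.2, 35.5]; rain shelter:
28.81 ± 3.10 in [21.8, 37.4]).  The second condition additionally gets a
+0.05 baseline offset and a common band-center shift δ = 15 nm — inside
the ±30 nm repeat window, so wavelength fusion is genuinely exercised.
Configurations whose maximum band depth (at the condition's SSC maximum)
would push reflectance non-positive are rejected.

What the generator does **not** emulate: wavelength-dependent (colored)
instrument noise, scattering/particle-size effects (no MSC/SNV-type
structure), nonlinear detector response, and band-shape changes beyond a
rigid center shift.  Consequently, noiseless synthetic reflectance is
exactly affine in SSC, so linear models can fit it perfectly — passing
tests demonstrate the algorithms' correctness and the update method's
mechanism, not field-level accuracy on real fruit.

## Conventions and numerical choices

* **Wavelength trimming** uses the closed interval [low, high]; a 1 nm grid
  trimmed to 450–2400 nm has exactly 1951 channels.
* **Baseline correction** subtracts each spectrum's own minimum (offset
  variant).  A linear-detrend alternative exists in commercial software;
  the offset reading was chosen and is flagged in the code as an
  interpretation.  Savitzky–Golay defaults to window 9, polyorder 2 —
  a common NIR smoothing choice; the pipeline default is no pretreatment,
  which the motivating comparison found competitive.
* **PLS1** is NIPALS with the coefficient path for all component counts
  produced in one pass (needed to keep the thousands of cross-validated
  sub-models in IRIV/SPA/update affordable).  At full rank it coincides
  with least squares on centered data (tested to 1e−8).  Component counts
  are capped at min(20, n_variables, smallest fold-train size − 1).
* **Cross-validation** assigns sample i to fold i mod folds in stored
  order — deterministic by construction; RMSECV pools residuals across
  folds (not a mean of per-fold RMSEs) and the chosen component count is
  the curve's argmin, ties to fewer components.  Default 10 folds.
* **Kennard–Stone** seeds with the lexicographically smallest farthest
  pair and breaks later ties to the lowest index; distances are computed
  on the spectra as given (no autoscaling).
* **IRIV**: binary sampling matrix with exactly n_rows/2 ones per column
  (default 500 rows; sub-model populations in the hundreds are standard
  for model population analysis); any all-zero row is repaired by pulling
  a 1 down a column from a donor row that keeps at least one variable,
  preserving exact column sums.  Exclusion sub-models reuse the same row
  minus the variable (paired design — this is what makes DMEAN
  interpretable).  The Mann–Whitney p-value is exact for tie-free samples
  of ≤8, otherwise the tie-corrected normal approximation; identical
  constant samples return p = 1.  DMEAN exactly 0 classifies as weak
  (retained).  Backward elimination is greedy best-first and stops when no
  single removal lowers RMSECV.  A sub-model with no variables left is
  scored as the intercept-only (fold-train mean) predictor.
* **SPA** mean-centers columns before projection; a candidate chain only
  displaces the incumbent if its CV-RMSE improves beyond numerical noise
  (1e−12 absolute / 1e−9 relative), so adding a variable that changes
  nothing never beats a shorter chain.  Chains are scored by
  OLS-with-intercept under the same interleaved CV; rank-deficient fits
  are skipped with a warning.
* **LS-SVM** uses K_ij = exp(−‖x_i−x_j‖²/σ²) and one dense LU solve of the
  bordered KKT system; the residual is checked (<1e−6 of the target
  scale).  The tuning grid is γ ∈ {10⁰…10⁶}, σ² ∈ {10⁻²…10⁴} (7×7,
  deterministic); ties go to smaller γ, then smaller σ².  Inputs are not
  autoscaled by default; a `scale` flag standardizes columns using
  calibration statistics only.
* **Wavelength fusion** uses a strict open window |Δ| < offset (default
  30 nm): a 29 nm-apart pair is deduplicated, a 30 nm-apart pair is not.
  Base-list wavelengths are never removed; this base-priority rule is
  inferred from the published worked example, in which every survivor of a
  cross-list near-duplicate pair is a base wavelength.  Surviving
  new-list wavelengths that conflict with each other resolve in favour of
  the earlier (more important) one.  An empty new list is allowed, which
  makes fusion idempotent.
* **Euclidean-distance update**: Kennard–Stone ranks the new-condition
  calibration samples in full-wavelength space (condition differences live
  in the whole spectrum), while the RMSECV that selects the number of
  added samples is computed on the fused wavelengths (the final model's
  variables).  m* is the trace argmin, ties to the smallest m; m = 0 (no
  augmentation) is available via `allow_zero`/`force_m` as an explicit
  ablation, since the selection rule itself does not consider it.
  The augmented set always contains every base-calibration sample.
* **Metrics**: headline R² is 1 − SS_res/SS_tot (squared Pearson
  correlation also reported); RPD divides the evaluated set's own
  reference SD (n−1 denominator) by RMSE, so RPD·RMSE equals that SD
  identically — the convention consistent with the published
  SD/RMSE/RPD triples (2.57/1.14 → 2.25; 2.84/2.54 → 1.12).

## Problem sizes in tests and examples

The test suite and examples run the generator at a 10 nm grid step (196
channels after trimming to 450–2400 nm) and the published sample sizes
(150 per condition, 114/36 Kennard–Stone split); the update-efficacy study
uses SPA selection (n_max 10) and 10 seeds, and the IRIV recovery study
uses 30 variables, 3 informative, n = 60, 100 sub-model rows, 10 seeds.
These sizes were chosen so the whole chain remains a desk-scale
computation while keeping every algorithmic path — selection, fusion,
ranking, augmentation, recalibration — at realistic dimensionality.

## Known limitations

* The generator's affine SSC→spectrum map means PLS can be exact on
  noiseless data; nonlinear benefits of the LS-SVM over PLS are therefore
  not demonstrated by the synthetic studies.
* IRIV's runtime grows as n_rows × n_variables cross-validated sub-model
  fits per iteration; at full 1951-channel resolution with 500 rows it is
  an overnight computation, which is why the pipeline exposes
  `n_rows`/`folds` and the studies run at reduced channel counts.
* The Mann–Whitney exact path is limited to tie-free samples of ≤8 per
  group; IRIV's usual sample sizes (n_rows/2 per group) always use the
  asymptotic path.
* Model serialization stores training spectra verbatim (LS-SVM needs them
  as support vectors); files scale with calibration size.
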