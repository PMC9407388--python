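# specfuse

Chemometrics for visible/near-infrared (VIS/NIR, 350–2500 nm) calibration of
fruit soluble-solids content (SSC, %), with a focus on the problem of **model
failure under a new measurement condition** — for example, a calibration
built on open-field-grown fruit collapsing on fruit grown under a rain
shelter.  The package is for spectroscopists and chemometricians who need a
calibration that stays valid across such condition changes without
collecting a full new reference set.

## What it implements

The full calibration chain, as a Python library with a thin `specfuse` CLI:

* **Kennard–Stone partitioning** — greedy maximin selection in Euclidean
  spectral space; the two mutually farthest samples seed the calibration
  set, then each step adds the candidate with the largest minimum distance
  `Dm` to the selected set.
* **PLS1 regression and RMSECV** — NIPALS partial least squares with a
  deterministic interleaved-fold cross-validation; RMSECV(c) is the pooled
  out-of-fold RMSE at each latent-variable count c.
* **IRIV variable selection** (iteratively retained informative variables) —
  model population analysis over a binary sampling matrix (each column
  exactly half ones).  Per variable i, `DMEAN_i` is the mean RMSECV of
  sub-models including i minus the same sub-models with i removed, and `P_i`
  a two-sided Mann–Whitney U p-value.  Variables classify as strong
  (DMEAN<0, P<0.05), weak (DMEAN<0, P≥0.05), interfering (DMEAN>0, P<0.05)
  or uninformative (DMEAN>0, P≥0.05); the last two are dropped each
  iteration, and a greedy backward elimination finishes the set.
* **SPA** (successive projections algorithm) — forward selection maximizing
  each candidate column's norm orthogonal to the span of those already
  chosen, scored over all start columns and chain lengths by
  cross-validated multiple-linear-regression RMSE.
* **LS-SVM regression** — RBF-kernel least-squares SVM: solving

  ```
  [ 0   1ᵀ         ] [ b ]   [ 0 ]
  [ 1   K + I/γ    ] [ α ] = [ y ],   K_ij = exp(−‖x_i − x_j‖² / σ²)
  ```

  with γ, σ² tuned on a deterministic log grid by cross-validated RMSE.
* **Wavelength fusion + Euclidean-distance model update** — the core
  method.  Selections from two conditions are merged; any new-condition
  wavelength strictly within ±30 nm of a base wavelength counts as a
  position-shifted repeat and is removed (base wins).  New-condition
  calibration samples are then ranked by Kennard–Stone on the
  full-wavelength spectra, the base set is augmented with the first m of
  them, and m is chosen at the minimum of the PLS RMSECV computed on the
  fused wavelengths.  An LS-SVM recalibrated on the augmented set serves
  both conditions.
* **Evaluation** — R² (1 − SS_res/SS_tot), RMSE and RPD
  (SD of the evaluated set's reference values / RMSE).
* **Synthetic data** — a two-condition VIS/NIR generator (Gaussian
  absorption bands near 970/1190/1450/1940 nm with SSC-dependent depths;
  the second condition adds a baseline offset and a ~15 nm band shift)
  so the whole chain is testable without instrument data.

## Worked example: wavelength fusion

```python
from specfuse import fuse_wavelengths

open_field = [957, 1008, 2339, 920, 2248, 2394, 1137, 1976, 647, 602]
rain_shelter = [1257, 962, 905, 1137, 2337, 2300, 1541, 2378, 2386,
                1947, 1907, 1480, 1058, 2128, 811, 693]
fused = fuse_wavelengths(open_field, rain_shelter, offset=30)
```

Running `python examples/wavelength_fusion.py` prints:

```
inputs : 10 base + 16 new wavelengths
fused  : 19 wavelengths
         602, 647, 693, 811, 920, 957, 1008, 1058, 1137, 1257, 1480, 1541, 1907, 1976, 2128, 2248, 2300, 2339, 2394
removed repeats (value -> anchor that displaced it):
         962 -> 957
         905 -> 920
         1137 -> 1137
         2337 -> 2339
         2378 -> 2394
         2386 -> 2394
         1947 -> 1976
```

The 26 input wavelengths collapse to 19: each removed value lay strictly
within 30 nm of its anchor (a position-shifted repeat of the same
absorption feature), and the shared 1137 nm is kept once.

## Worked example: model update on synthetic data

`python examples/model_update.py` builds the full chain on the synthetic
two-condition study and prints:

```
fused 12 wavelengths from 8+10 (6 repeats within 30 nm removed)
added 114 of 114 new-condition samples (min RMSECV 0.597%)
set                             n      R2   RMSE%    RPD
--------------------------------------------------------
before/open_field              36   0.939   0.537   4.12
before/rain_shelter            36 -42.565  13.715   0.15
updated/open_field             36   0.932   0.570   3.88
updated/rain_shelter           36   0.974   0.335   6.29
```

Before the update, the base-condition model is useless on the shifted
condition (negative R², RPD 0.15); after wavelength fusion and sample
augmentation both conditions are predicted well, at a small cost
(~6% RMSEP) on the base condition.

## Pipeline / CLI

```sh
specfuse run --config config.yaml --out runs/demo
```

executes simulate → trim/preprocess → split → select → fuse → update →
train → evaluate, writing every intermediate artifact (CSV/JSON) so each
stage can be re-run in isolation (`specfuse simulate|split|preprocess|
select|fuse|update|train|predict|evaluate`).  Re-runs with the same seed
are byte-identical.

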