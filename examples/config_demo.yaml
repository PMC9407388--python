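# Desk-scale demo configuration for `specfuse run`.
# Coarse 25 nm sampling and SPA-only selection keep the full pipeline
# (simulate -> split -> select -> fuse -> update -> train -> evaluate)
# under a few seconds; remove the overrides to run at full resolution.
# Set `update: null` to produce the wavelength-fusion-only ablation.
seed: 1
simulate:
  n_samples: 60
  grid_step: 25.0
  noise_sd: 0.005
split:
  n_cal: 45
select:
  method: spa
  spa_n_max: 6
  folds: 5
update:
  folds: 5
train:
  folds: 5
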