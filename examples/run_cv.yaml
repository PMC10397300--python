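# Example run configuration for `burnganext cv --config examples/run_cv.yaml`
# (also accepted by `burnganext train`).  A small synthetic dataset is
# generated on the fly; point `manifest:` at a manifest.csv instead to use
# images on disk.
task: degree          # degree (3-way) or graft (binary)
seed: 11
out_dir: scratch/cv_run
k: 5
synth:
  n_per_class: 40
  height: 48
  width: 48
  seed: 11
model:
  preset: burnganext50
  width_multiplier: 0.125
  cardinality: 4
  input_shape: [3, 48, 48]
training:
  learning_rate: 2.0e-3
  batch_size: 16
  epochs: 8
# augment:            # optional: expands the training split only
#   transforms: [hflip, vflip, rot+30, rot-30]
#   include_original: true
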