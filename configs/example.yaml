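# Example end-to-end study configuration (desk scale).
# Run with: trabeculagen run --config configs/example.yaml
output_dir: runs/example
seed: 0
n_train: 2
n_test: 1
phantom:
  # small vertebra keeps the demo quick; morphometry targets are the
  # defaults (BV/TV 0.18, Tb.Th 0.218 mm at 52 um voxels)
  extent_mm: [1.56, 10.0, 10.0]
  body_semiaxes_mm: [4.4, 4.6]
  canal_radius_mm: 1.2
  gt_region_mm: [1.2, 4.0, 4.0]
pairing:
  lowe_ratio: 0.75
training:
  iterations: 300
  image_size: 64
  base_channels: 6
  lambda_r: 0.1
  lambda_f: 1.0
  lr: 1.0e-4
voi:
  mode: center
  diameter_mm: 3.0
  height_mm: 1.2
evaluation:
  scopes: [overall]
  extractor_seed: 0
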