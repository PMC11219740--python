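# Full-scale study settings (phantom mode).
# Scaled-down runs only need to shrink n_slices, ffo.population_size,
# ffo.iterations, train.epochs and folds.

n_slices: 500
class_balance: 0.51        # 255 HGG-like vs 245 LGG-like
image_size: 200
tumor_radius: 18.0
noise_sd: 5.0
band_intensities: [60.0, 110.0, 160.0]

tau: 0.05                  # background binarization threshold
resize_to: 200
equalize: true

ffo:
  population_size: 150
  iterations: 500
  K: 5
  kmeans_fraction: 0.25
  min_region_fraction: 0.05

roi:
  intensity_k: 1.0
  min_area_fraction: 0.002
  max_area_fraction: 0.3
  patch_size: 200

lbp:
  P: 8
  radii: [1.0, 2.0]
  grid: [4, 4]

train:
  lr0: 0.005
  batch_size: 32
  epochs: 100
  weight_decay: 0.0001
  lr_decay: 0.9
  grad_clip: 1.0
  mode: fused

folds: 10
seed: 0
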