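seed: 17
log_level: INFO
phantom:
  grid_shape:
  - 32
  - 32
  - 32
  spacing_mm: 0.5
  n_teeth: 3
  noise_sigma: 0.02
  n_samples: 4
  prevalence: 0.5
  volume_range_mm3:
  - 15.0
  - 40.0
pipeline:
  margin_mm: 2.0
  target_spacing_mm: 0.5
  input_shape:
  - 32
  - 32
  - 32
  min_lesion_volume_cm3: 0.001
  dilation_radius_voxels: 1
network:
  n_levels: 3
  base_channels: 2
training:
  n_steps: 50
  batch_size: 2
  lr: 0.001
observers:
  unaided:
    observer1:
      sensitivity: 0.75
      specificity: 0.95
      seed: 11
    observer2:
      sensitivity: 0.77
      specificity: 0.94
      seed: 12
    observer3:
      sensitivity: 0.76
      specificity: 0.73
      seed: 13
  aided:
    observer1:
      sensitivity: 0.87
      specificity: 0.97
      seed: 21
    observer2:
      sensitivity: 0.87
      specificity: 0.97
      seed: 22
    observer3:
      sensitivity: 0.88
      specificity: 0.92
      seed: 23
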