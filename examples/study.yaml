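# Example desk-scale study configuration for `radbatch run`.
# Any omitted key falls back to the package defaults (radbatch.pipeline.DEFAULT_CONFIG).
seed: 17

phantom:
  materials: all        # or a list of material ids, e.g. [water, brain, liver]
  rod_diameter: 6.0     # mm
  grid_spacing: 0.35    # mm, ground-truth voxel size (<= 0.5)
  rod_height: 10.0      # mm

baseline:               # protocol around which each variable is swept
  voltage: 120.0        # kV
  current: 200.0        # mAs
  slice_thickness: 2.0  # mm
  slice_spacing: 1.0    # mm
  pixel_size: 0.78      # mm
  kernel_id: A

sweeps:                 # one-variable-at-a-time protocol grid
  pixel_size: [0.39, 0.78, 1.0]
  slice_spacing: [1.0, 1.25, 2.0, 2.5, 5.0]
  slice_thickness: [2.0, 3.0, 5.0]
  kernel_id: [A, B, C, D, E]
  voltage: [90.0, 120.0, 140.0]
  current: [100.0, 200.0, 400.0]

features:
  bin_width: 50.0       # HU
  target: 1.0           # mm isotropic resampling target
  also_native: true     # extract a second table without resampling

robustness:
  icc_threshold: 0.8    # feature robust when ICC > 0.8
  rule_threshold: 80.0  # variable is a batch when < 80% features robust

evaluation:
  materials: [brain, liver]   # the two similar-density rods to cluster
  cross:                      # thickness x kernel grid for the purity stage
    slice_thickness: [2.0, 3.0, 5.0]
    kernel_id: [A, B, C, D, E]
  k: 2
  iterations: 1000
  freq_threshold: 0.2
  svd_alpha: 0.001

clinical:
  enabled: true
  n_features: 93
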