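# Demo protocol: one reference scan, a normal-breathing repeat, a deeper
# ("~25% deeper" instruction) and a shallow scan, mirroring the repeated
# free-breathing acquisition scheme the package targets (NB = normal
# breathing, IB = irregular breathing, aB = after break).
seed: 20230403
output_dir: artifacts
phantom:
  grid_size: [96, 96]
  n_frames: 160
  frame_interval: 0.310
  pixel_spacing: 3.91
  respiratory_freq: 0.25
  cardiac_freq: 1.1
  noise_sigma: 2.0
scans:
  - id: reference
    breathing: NB
    breathing_depth: 1.0
    reference: true
  - id: NB2
    breathing: NB
    breathing_depth: 1.0
  - id: IB
    breathing: IB
    breathing_depth: 1.25
  - id: IB_aB
    breathing: IB aB
    breathing_depth: 0.8
processing:
  discard: 20
  registration: none
  cutoff: auto
  filter_order: 4
normalization:
  methods: [uncorrected, factor, roi]
  roi_label: 6
  roi_size: 12
  perfusion_roi_label: 5
evaluate:
  alpha: 0.05
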