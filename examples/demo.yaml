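# Reduced-size two-visit synthetic study (2.4 x 2.4 mm field, 4 volumes)
protocol:
  fov_mm: 1.536
  ascans_per_bscan: 128
  bscans_per_volume: 128
  volume_duration_s: 0.8
  inter_volume_gap_s: 0.02
  n_volumes: 4
phantom:
  nz: 220
  undulation_amp_um: 20.0
  n_sdds: 12
  n_drusen: 1
motion_sim:
  drift_sd_um: 6.0
  axial_sd_um: 3.0
  saccade_rate_hz: 0.0
noise:
  speckle_contrast: 0.2
  detector_noise_sd: 0.005
  bias_amp: 0.15
followup:
  enabled: true
  n_stable: 6
  n_regress: 1
  n_fuse_pairs: 1
  n_new: 1
  shift_um: [24.0, -12.0]
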