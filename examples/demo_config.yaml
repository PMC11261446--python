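# Two-mode demonstration run: 20 s of cyclic dropwise sweating followed
# by 20 s of filmwise sweating on a small (96 px)² patch, with the
# matching simulated humidity-probe record. Every stage of
# `perspire all --config examples/demo_config.yaml` reads and writes
# inside output_dir.
seed: 7
output_dir: demo_run

scene:
  width_px: 96
  height_px: 96
  duration_s: 20
  onset_ramp_s: 20
  shake_amplitude_px: 2.0
  film_thickness_map: [0.0009]

simulation:
  kind: two_mode
  h_m_dropwise: 0.012
  h_m_filmwise: 0.004
  flux_noise_frac: 0.02

probe:
  flow_schedule: [[0.0, 0.1]]
  probe_time_constant_s: 1.0
  capsule_mixing_time_constant_s: 2.0
  evaporation_area_cm2: 1.93

segmentation:
  - start_s: 0
    end_s: 20
    mode: dropwise
    method: phansalkar
    radius: 20
    rethreshold_level: 0.7
  - start_s: 20
    mode: filmwise
    method: midgrey
    radius: 35
    midgrey_open_px: 2
    midgrey_min_contrast: 0.15
    morphology: [close, dilate, dilate, fill_holes]
    rethreshold_level: 0.5

tracking:
  min_frames: 3
  cluster_radius_mm: 0.3

analysis:
  surface_temperature_c: 34.0
  ambient_temperature_c: 24.0
  ambient_relative_humidity: 0.30
  total_area_cm2: 1.93
  mode_windows:
    dropwise: [2.0, 20.0]
    filmwise: [28.0, 40.0]

uncertainty:
  n_replicates: 3
  confidence: 0.95
  u_cout_gm3: 0.18
  flow_full_scale_lpm: 1.0
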