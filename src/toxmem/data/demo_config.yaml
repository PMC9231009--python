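# Demo run configuration: small synthetic system, every stage enabled.
output_dir: runs/demo

seeds:
  simulate: 11
  diffusion: 12
  metad: 13
  energetics: 14

bilayer:
  n_lipids: 308
  popg_fraction: 0.25      # 3:1 POPC:POPG
  head_roughness_sigma: 0.05
  n_frames: 300
  frame_dt: 2.0            # ns

binding:
  start_distance: 2.5      # nm above the upper leaflet
  onset_frame: 60
  patch_depth: -0.3        # nm below the head plane for the inserting patch
  other_depth: 0.6
  depth_noise_sigma: 0.1

insertion:
  criterion: residue_com
  gate_nm: 0.5

dipole:
  bin_deg: 5.0
  distance_bin_nm: 0.25

diffusion:
  D3: 1.0e-6               # cm^2/s, bulk
  D2: 4.1e-8               # cm^2/s, lateral
  n_steps: 50000
  dt_ps: 10.0
  max_lag_fraction: 0.002
  fit_lo: 0.1
  fit_hi: 0.5
  psd:
    box_L_nm: 16.0

metad:
  W0: 0.5                  # kcal/mol
  hill_width: 0.1
  delta_T: 1500.0          # K
  stride: 200
  n_steps: 200000
  barrier: 3.0             # kcal/mol double-well barrier
  walls: [-1.6, 1.6]
  wall_k: 10.0
  dt: 0.005
  x0: -1.0

rdmodel:
  kp_min: 1.0e-2
  kp_max: 1.0e+6
  n_kp: 49
  d2_list: [4.1e-8, 1.0e-9, 1.0e-10]

energetics:
  n_frames: 2048
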