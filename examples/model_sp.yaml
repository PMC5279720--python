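mode: SP
scenario: two_zone_morphogen
ITW: 4
n_columns: 14
n_rows: 6
t0: 10.7
t_end: 12.7
dt: 0.005
snapshot_dt: 0.1
burn_in: 1.0
seed: 0
replicate_count: 16
elements_per_cell: 4
schedule: null
forces:
  morse_intra:
    depth: 1.0
    equilibrium_distance: 0.5
    range: 0.8
  morse_adhesion:
    depth: 0.3
    equilibrium_distance: 1.0
    range: 0.4
  repulsion:
    amplitude: 0.5
    range: 0.5
  cutoff: 2.0
  drag: 1.0
  element_noise: 0.2
  strength_scale: 1.0
genes:
  C_A: 3.3
  C_B: 2.52
  n_A: 2.0
  n_B: 2.0
  m_A: 1.0
  m_B: 4.0
  K_A: 0.1
  K_B: 0.1
  chi_A: 0.6
  chi_B: 1.3
  kappa_A: 0.9
  kappa_B: 50.0
  d_A: 15.0
  d_B: 15.0
  k_M: 5.0
  S_params:
    V_S: 2.0
    K_S: 1.0
    h_S: 2.0
  eta_in: 0.15
  eta_A: 0.06
  eta_B: 0.06
  tau: 1.0
  kappa_B_low: 0.0
  K_low: 0.4
  h_low: 4.0
morphogen:
  D: 10.0
  beta: 1.0
  k_M: 5.0
  production:
    V_max: 3.83
    profile: exponential
    length_scale: 9.33
  eta_out: 0.25
  dx: 0.5
  plasticity_window:
  - 0.0
  - 14.0
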