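# Default generating model for synthetic community mapping datasets.
# Backbone growth parameters follow the co-culture mean-curve scale of the
# two-species bacterial experiment the generator emulates (carrying
# capacities near 24 and 21.6 abundance units, rates near 0.2-0.3 per hour,
# mutually antagonistic interaction scalars, 16 observation times over 36 h).
# The effect/covariance shape parameters were fixed once by a noncentrality
# design calculation (see docs/methods.md) and are not tuning knobs.
n_pairs: 45
n_markers: 1000
causal_a: 0
causal_b: 0
time_grid:
  start: 2.25
  end: 36.0
  points: 16
h2: 0.05
allele_freq: 0.5
base_theta:
  r_e: 0.25
  K_e: 23.94
  alpha_es: -0.08
  r_s: 0.22
  K_s: 21.56
  alpha_se: -0.12
init: [0.8, 0.8]
effect_r: 0.08
effect_K: 0.08
effect_alpha: 0.25
sad:
  phi_e: 0.77
  phi_s: 0.77
  nu_e: 1.0
  nu_s: 1.0
  rho: 0.3
seed: 0
solver_step: 0.02
ensure_filled_cells: true
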