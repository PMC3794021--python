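params:
  T: 11260000000.0
  alpha: 0.4
  zeta: 0.9
  gamma: 0.4
  beta: 0.01
  delta: 1.0
  total_land_with_barren: 13247058823.529411
  preag_forest_frac: 0.575
drivers:
  p:
    x0: 310000000.0
    K: 10500000000.0
    r: 0.032
    tI: 1998.3
  c:
    x0: 571.0
    K: 1940.0
    r: 0.019
    tI: 1995.8
  y:
    x0: 150.0
    K: 3391.0
    r: 0.039
    tI: 1995.7
  s: 0.06
numerics:
  t_start: 1000.0
  dt: 0.1
  horizon_cap: 2000.0
  record_every: 1.0
  reexpand_from_abandoned: false
scan:
  n_ky: 30
  n_kc: 30
  t_e: 2009.0
  lo_factor: 1.02
  hi_factor: 3.0
seed: 0
output_dir: null
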