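# Aliev-Panfilov two-variable model, standard parameter set
# (Aliev & Panfilov, Chaos Solitons Fractals 1996). Dimensionless units.
model: ap
param_set: standard
params:
  k: 8.0
  a: 0.15
  eps0: 0.002
  mu1: 0.2
  mu2: 0.3
# simulation defaults (dimensionless space/time)
defaults:
  P11: 1.0
  dx: 0.5
  dt: 0.0029
  V_star: 0.5
  R_star: 1.0
  dt_lat: 1.0
  dt_c: 10.0
  dphi_arr_crit: 0.7
  tau: 20.0
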