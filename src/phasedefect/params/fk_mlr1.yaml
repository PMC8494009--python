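# Fenton-Karma three-variable model, MLR-I parameter set
# (Fenton & Karma, Chaos 1998, Table 1). Times in ms, space in mm.
# tau_d = Cm / g_fi_bar with Cm = 1 uF/cm^2, g_fi_bar = 5.8 ms^-1.
model: fk
param_set: mlr1
params:
  tau_d: 0.17241379310344829   # 1/5.8
  tau_r: 130.0
  tau_si: 127.0
  tau_0: 12.5
  tau_vp: 10.0
  tau_vm1: 18.2
  tau_vm2: 18.2
  tau_wp: 1020.0
  tau_wm: 80.0
  u_c: 0.13
  u_v: 0.0
  u_csi: 0.85
  k: 10.0
defaults:
  P11: 0.1          # mm^2/ms
  dx: 0.262         # mm
  dt: 0.16          # ms
  V_star: 0.5
  R_star: 0.8       # R = 1 - v
  dt_lat: 1.6       # ms
  dt_c: 16.0        # ms
  dphi_arr_crit: 2.0
  tau: 70.0         # ms
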