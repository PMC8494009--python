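# Fenton-Karma three-variable model, MBR (modified Beeler-Reuter) set
# (Fenton & Karma, Chaos 1998, Table 1). Times in ms, space in mm.
model: fk
param_set: mbr
params:
  tau_d: 0.25       # Cm/g_fi_bar = 1/4
  tau_r: 50.0
  tau_si: 44.84
  tau_0: 8.3
  tau_vp: 3.33
  tau_vm1: 1000.0
  tau_vm2: 19.2
  tau_wp: 667.0
  tau_wm: 11.0
  u_c: 0.13
  u_v: 0.055
  u_csi: 0.85
  k: 10.0
defaults:
  P11: 0.1
  dx: 0.31          # 3D grid spacing used with this set
  dt: 0.1
  V_star: 0.5
  R_star: 0.8
  dt_lat: 1.6
  dt_c: 16.0
  dphi_arr_crit: 2.0
  tau: 70.0
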