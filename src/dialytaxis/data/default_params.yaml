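# Default micro-reactor chemistry: urease-loaded BSA condensate in
# phosphate-buffered urea solution.  Diffusivities in pure water and the
# acid-base constants of the five-reaction network; quantities either bare
# SI numbers or tagged with explicit units.
species:
  D_w:
    urea: 1.38e-9
    NH3: 1.50e-9
    NH4+: 1.96e-9
    CO2: 1.67e-9
    HCO3-: 1.19e-9
    H+: 9.31e-9
    OH-: 5.27e-9
    HPO4^2-: 0.76e-9
    H2PO4-: 0.96e-9
equilibria:
  pKa2: 9.25   # NH4+/NH3
  pKa3: 6.35   # CO2/HCO3-
  pKw: 14.0
  pKa5: 7.21   # H2PO4-/HPO4^2-
kinetics:
  k_cat: 4400 1/s
  K_m: 23 mM
  c_e_dense: 1 uM
phases:
  eta_dense: 0.8 Pa.s
  eta_dilute: 24 mPa.s
  eta_water: 1 mPa.s
  R: 25 um
  sharpness: 100
far_field:
  pH_inf: 6.8
  total_phosphate: 100 mM
  c_s: 100 mM
solver:
  domain_factor: 50
  n_nodes: 260
  tol: 1.0e-8
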