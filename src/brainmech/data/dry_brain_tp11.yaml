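# Dry-brain constants of the ISV viscoplasticity material-point model.
# Stresses in MPa, rates in 1/s; keys match MaterialConstants field names.
shear_modulus: 0.80
bulk_modulus: 399.73
ref_shear_rate: 120000.0
rate_sensitivity: 0.90
yield_stress: 9.00
pressure_sensitivity: 0.0
locking_stretch: 2.00
rubbery_modulus: 0.07
beta_hardening: 1.4
h0: 0.41
g0: 0.3
h1: 0.0
xi1_init: 0.0045
xistar_init: 1.2
xistar_sat: 0.001
xi2_init: 0.0
xi2_sat: 0.4
c_kappa1: 0.41
c_kappa2: 0.0
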