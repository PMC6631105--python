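# Hugoniot-form Mie-Gruneisen parameters for water at standard conditions
# (linear shock-velocity/particle-velocity fit Us = c0 + s * Up).
rho0: 1000.0     # kg/m^3
c0: 1480.0       # m/s
s: 1.979
gamma0: 0.11
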