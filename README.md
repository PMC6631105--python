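# brainmech

Desk-scale computational mechanics of brain tissue hydration: how the water
content of brain parenchyma shapes its compressive response from
quasi-static (0.00625 1/s) to impact (750 1/s) strain rates.

Traumatic brain injury modelling needs constitutive descriptions of brain
tissue at the strain rates of real head impacts. Native ("wet") brain is
~80% water by mass and behaves very differently from lyophilized ("dry")
brain matrix: wet tissue shows a rate-sensitive initial hardening peak at
high rates and polymer-like concave-up hardening at low rates, while the
dry matrix behaves like a ductile solid — elastic toe, yield point, work
hardening — almost independent of rate. This package implements the
computational machinery needed to study that contrast: a material-point
constitutive model for the dry matrix, an equation of state for water, a
virtual split-Hopkinson pressure bar (SHPB), mixture homogenization over
water/dry-matrix compositions, model calibration, and the curve metrics and
rate statistics used to summarize compression tests. A synthetic-data
generator stands in for laboratory data so every stage is testable.

## The models

**Dry brain — internal-state-variable (ISV) viscoplasticity** (the
MSU TP 1.1 thermoplastic model family), reduced to uniaxial
true-strain-rate-controlled compression. With `F = Fe Fp` and logarithmic
elastic strain `Ee = ln(Ue)`:

    M      = 2 mu Ee + (K - 2 mu/3) tr(Ee) I                 Mandel stress
    tau    = (1/2) ||dev(M - alpha)||,   pi = -tr(M)/3
    gdot_p = gdot0p [ sinh( < tau - (k1 + k2 + a_p pi) > / Y ) ]^m

Hardening enters through two internal strains (`k1 = C_k1 xi1`,
`k2 = C_k2 xi2`) that evolve with the plastic shear rate toward evolving
saturation thresholds, and an eight-chain back stress `alpha` built from a
stretch-like tensor `beta` with inverse-Langevin locking at the network
locking stretch `lambda_L`. The packaged default constants are the
calibrated dry-brain set (mu = 0.80 MPa, K = 399.73 MPa, Y = 9.00 MPa,
m = 0.90, gdot0p = 1.2e5 1/s, mu_R = 0.07 MPa, lambda_L = 2.0, ...).

**Water — Mie-Gruneisen EOS in Hugoniot form**, from the linear shock
velocity/particle velocity fit `Us = c0 + s Up`:

    p(eta) = rho0 c0^2 eta / (1 - s eta)^2 * (1 - Gamma0 eta / 2),
    eta = 1 - rho0/rho

**Virtual SHPB** — 1-D elastic wave propagation through the
striker/incident/transmitted polycarbonate bar train (E = 2391.2 MPa,
nu = 0.36) with the specimen as a lumped nonlinear interface, plus the
classical Kolsky reduction: specimen strain rate `-2 c_b eps_r / L_s`,
stress `(A_bar/A_spec) E_bar eps_t`.

**Mixture homogenization** — subcells randomly assigned water or dry-brain
behavior at a target water mass fraction, averaged iso-strain (Voigt; an
iso-stress Reuss rule is available) to give the specimen-average stress as
a function of hydration.

## Worked example

```python
import brainmech as bm

# dry-brain response at an impact-relevant rate
curve = bm.simulate_uniaxial(rate=250.0, max_strain=0.30)
print(f"E = {bm.elastic_modulus(bm.DRY_BRAIN):.4f} MPa")
for eps in (0.05, 0.10, 0.30):
    print(f"stress at {eps:.0%} strain: {curve.stress_at(eps):7.1f} kPa")

# hydration sweep: average stress falls as water content rises
sweep = bm.mixture_sweep(rate=250.0, seed=0)
for frac, mix in sorted(sweep.curves.items()):
    print(f"{frac:.0%} water m/m: {mix.stress_at(0.10):6.1f} kPa at 10% strain")
```

prints

```
E = 2.3984 MPa
stress at 5% strain:    59.1 kPa
stress at 10% strain:    77.7 kPa
stress at 30% strain:   134.8 kPa
20% water m/m:   59.8 kPa at 10% strain
40% water m/m:   43.2 kPa at 10% strain
60% water m/m:   27.7 kPa at 10% strain
80% water m/m:   13.4 kPa at 10% strain
```

The initial slope equals the closed-form Young's modulus
`9 K mu / (3K + mu)` of the elastic law; the sinh flow rule then bends the
curve over into rate-dependent plastic flow near 3% strain. In the mixture
sweep the water subcells carry no quasi-1-D strength, so specimen-average
stress is inversely related to hydration — the computational counterpart of
the observation that the driest specimens carry the highest stress.

A CLI wraps the same stages:

```
brainmech simulate-material --rate 250 --out dry.csv
brainmech shpb simulate --out gauges.csv
brainmech shpb reduce --gauges gauges.csv --out reduced.csv
brainmech mixture sweep --rate 250 --fractions 0.2,0.4,0.6,0.8 --out sweep.csv
brainmech run-all --out-dir out --seed 0
```

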