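# Methods

This note documents the models, numerical choices and declared defaults of
`brainmech`, and what its synthetic-data tests do and do not demonstrate
about real tissue data.

## 1. ISV viscoplasticity material point (`constitutive`)

### Model

The dry-brain matrix is modelled with a finite-strain internal-state-
variable (ISV) viscoplasticity model of the thermoplastic (MSU TP 1.1)
family. Kinematics use the multiplicative split `F = Fe Fp` with an
axisymmetric diagonal representation (uniaxial stress): axial and lateral
principal stretches for both elastic and plastic parts. The elastic law is
written on the Hencky strain `Ee = ln(Ue)`:

    M = 2 mu Ee + (K - 2 mu/3) tr(Ee) I

Flow is driven by the equivalent shear stress of the Mandel stress minus an
eight-chain back stress,

    tau = f ||dev(M - alpha)||,        f = 1/2 (default)
    pi  = -tr(M)/3                     (compression positive)
    gdot_p = gdot0p [sinh(<tau - (k1 + k2 + a_p pi)>/Y)]^m

with flow direction `Np = dev(M - alpha)/||dev(M - alpha)||` and plastic
rate of deformation `Dp = f2 gdot_p Np` (`f2 = 1/2` by default). Both 1/2
prefactors can be switched to `1/sqrt(2)` — the convention of part of the
source constitutive-model literature — through
`simulate_uniaxial(shear_invariant_factor=..., flow_rate_factor=...)`; the
default follows the printed form of the model equations. The distinction is
absorbed into the calibrated constants either way.

ISV evolution:

    xi1' = h0 (1 - xi1/xi*) gdot_p            k1 = C_k1 xi1
    xi*' = g0 (1 - xi*/xi*_sat) gdot_p
    xi2' = h1 (lam_p - 1)(1 - xi2/xi2_sat) gdot_p,   k2 = C_k2 xi2
    beta' = Rs1 (Dp beta + beta Dp),          beta(0) = I

The free energy behind the conjugates is not specified by the model
summary, so the conjugates are taken linear (`k = C xi`), consistent with
the `C` constants carrying stress units. `lam_p` is taken as
`sqrt(tr(Bp)/3)` so that it equals 1 at zero plastic strain and the
`(lam_p - 1)` factor vanishes initially; the literal `tr(Bp)/3` variant is
available via `lambda_p_rule="literal"`. At the default constants
(`h1 = 0`, `C_k2 = 0`) the xi2 branch is inert either way.

The back stress is an eight-chain network stress: with chain stretch
`lam_c = sqrt(tr(beta)/3)`,

    alpha = (mu_R/3) (lambda_L/lam_c) Linv(lam_c/lambda_L) dev(beta)

using the Cohen/Pade approximant `Linv(x) = x(3 - x^2)/(1 - x^2)` (accurate
to a few percent over the usable range; cross-checked in the tests against
numerical inversion of the Langevin function). `alpha = 0` at `beta = I`;
chain stretch at or beyond `lambda_L` raises a locking error.

A noteworthy consequence of the published constant set: the energetic
strain barrier starts at `xi*_0 = 1.2` but saturates at `xi*_sat = 0.001`
with `g0/xi*_sat = 300`, so `xi*` collapses within the first ~1% of plastic
shear and `k1` hardening is a small transient. The sustained large-strain
hardening of the simulated curves comes from the eight-chain back stress.
This is the literal reading of the constants and is flagged here rather
than "fixed".

### Integration

`simulate_uniaxial` advances the prescribed axial true strain at a constant
rate and, each step, applies an elastic predictor followed by a plastic
corrector:

* **Lateral equilibrium.** With Hencky elasticity the lateral-stress-free
  condition is exactly linear in the lateral elastic log strain
  (`e_l = -nu e_a`, `nu = (3K - 2mu)/(2(3K + mu))`), so the lateral stretch
  is obtained in closed form rather than by iteration. The reported axial
  true (Cauchy) stress is `-M_a / Je`.
* **ISV updates.** The scalar ISV ODEs are linear in the ISV with
  coefficients frozen over the step, so they are advanced by their exact
  exponential relaxation toward saturation. This matters because the
  published `g0/xi*_sat` ratio makes the xi* equation stiff; the
  exponential update is unconditionally stable and reduces to forward
  Euler for small increments.
* **Plastic stretches and beta** use exponential (volume-exact) updates
  `lam <- lam exp(Dp_ii dt)` and `beta <- exp(Rs1 Dp dt) beta exp(Rs1 Dp dt)`,
  so `det(Fp) = 1` holds to machine precision for the traceless flow
  direction.
* **Step size.** Default `dt = min(1e-4, max(1e-7, 2.5e-5/rate))` —
  ~2.5e-5 strain per step, i.e. 1e-7 s at 250 1/s and 1e-4 s at
  quasi-static rates, both overridable. Halving the step changes the
  250 1/s stress at 10% strain by ~0.03% (the 1-D analogue of a mesh
  refinement study; asserted at <0.5% in the tests).

Stresses are MPa internally; curves are reported in kPa with compression
positive, matching the reporting convention of tissue compression tables.

## 2. Water EOS

Hugoniot-form Mie-Gruneisen pressure at volumetric compression
`eta = 1 - rho0/rho`:

    p = rho0 c0^2 eta (1 - s eta)^-2 (1 - Gamma0 eta/2)

Parameters are not part of the published constant set; the packaged
defaults are standard water Hugoniot values (rho0 = 1000 kg/m^3,
c0 = 1480 m/s, s = 1.979, Gamma0 = 0.11), configurable via
`data/water_eos.yaml`. The pole at `eta = 1/s` is rejected explicitly.

## 3. Virtual SHPB (`shpb`)

The bar train is discretized as 1-D lumped-mass chains (default element
0.002 m) integrated by symplectic Euler (equivalent to central difference).
The striker contacts the incident bar through a compression-only penalty
spring of one element stiffness; `"welded"` couples incident and
transmitted bars rigidly for impedance-matched transmission checks. The
specimen is a zero-length nonlinear interface: nominal strain
`(u_in - u_tr)/L_s`, force from the user handle `stress(strain, rate)` on
the specimen area, no tension. Bars are purely elastic (polycarbonate,
E = 2391.2 MPa, nu = 0.36, rho = 1200 kg/m^3 by default); no viscoelastic
dispersion correction is attempted, and bar lengths/striker velocity are
declared defaults (striker 0.6 m, bars 1.8 m, 38 mm diameter), not inferred
values.

The default time step is 0.5x the bar CFL bound `dx/c`: the penalty
junctions raise the largest local eigenfrequency to about `2.45 sqrt(k/m)`,
above the interior-chain limit `2 sqrt(k/m)`, so integrating at the plain
CFL step is unstable at the contact. User-supplied steps are validated
against `dx/c` and rejected with the required step. The discrete chain is
mildly dispersive: sharp wave fronts carry ~Gibbs-like ringing at the
element scale. This does not bias the Kolsky reduction (which integrates
the signals) but it is why the force-balance diagnostic smooths the ratio
(20 us boxcar) and masks samples below 5% of peak specimen stress before
flagging departures from unity.

Reduction follows the one-wave Kolsky formulas on a face-time base located
by fixed geometric time shifts (no peak detection); a three-wave variant
averages front and back face forces. Windows are validated against
incident/reflected overlap at the gauge. Wave-speed measurement places two
virtual gauges on the incident bar and times the first passage by
50%-of-peak threshold crossings; `E = rho c^2` recovers the configured bar
modulus within 0.5% at the default discretization.

## 4. Mixture homogenization (`mixture`)

The full 3-D FE mixture study is replaced by subcell averaging: `n = 1000`
equal-volume subcells are labelled water or dry at the volume fraction
converted from the target mass fraction
(`v = (w/rho_w) / (w/rho_w + (1-w)/rho_d)`; dry density default
1200 kg/m^3, declared). Iso-strain (Voigt) averaging sums subcell stresses;
an iso-stress (Reuss) rule inverts the phase curves on a common stress
grid. Voigt >= Reuss holds by construction and is asserted.

**Water subcell response.** Under the common-axial-strain assumption a
subcell that is laterally unconstrained and has zero deviatoric strength
supports no axial stress — it bulges at constant volume — so the default
water model contributes zero strength and the specimen-average stress
decreases monotonically with water fraction, as the hydration-sweep
observations require. A fully confined water column would instead respond
with the EOS pressure at the full volumetric compression, which at 10%
strain is ~300 MPa — three orders stiffer than the dry matrix — and would
invert the ordering; that limit (and anything between) is available via
`water_subcell_model(lateral_confinement=...)`. The inertial stiffening
that water contributes in a real high-rate test is wave physics and lives
in the `shpb` module, not in the quasi-1-D mixture rule.

## 5. Calibration (`calibration`)

Least squares on the material-point simulator: the loss is the sum of
squared stress misfits (kPa^2) on each target curve's strain grid, with the
model curve sampled densely and interpolated by a cubic spline so grid
mismatch is negligible (self-residual ~1e-27). A relative (per-curve
normalized) loss is available for unit-free fitting. The optimizer is
Nelder-Mead on log-scaled parameters with bounds — derivative-free because
the explicit simulator is only piecewise-smooth in its constants, and
log-scaling because the constants are positive and span decades. Freeing
the rate-sensitivity exponent requires curves at two or more distinct
rates; the pairs (C_k1, h0) and (mu, K) are rejected as jointly free by
default because a single uniaxial curve cannot separate them. Noise-free
round trips recover mu, Y, mu_R and m to well under 1%; with 5%
multiplicative noise, mu is recovered within a few percent (asserted at
10%).

## 6. Curve metrics and statistics (`mech_analysis`)

* **Tangent modulus**: central difference of linearly interpolated stress
  over a symmetric +/-0.5% strain window — exact for quadratics when the
  window endpoints are sample points. Default evaluation strain is 5%; the
  quasi-static wet reporting convention uses 1%, and both are supported
  (`tangent_at=`).
* **Transition point**: at high rates, the first interior local stress
  maximum (the initial hardening peak sigma_p) with a 2%-of-peak prominence
  guard against noise spikes; absence raises an explicit not-found error.
  Quasi-static sigma_t is operationalized as the stress at 5% true strain
  (the curves are treated as elastic-inelastic beyond that strain). An
  offset-yield rule (initial slope offset by 0.2% strain) serves ductile,
  monotone curves such as dry brain, which have no interior peak.
* **Statistics**: classical one-way ANOVA (degenerate zero-within-variance
  input rejected), pairwise two-sample t tests, and a hand-implemented
  step-down Holm-Sidak procedure (threshold `1 - (1-alpha)^(1/(k-i+1))` at
  ascending rank i, stopping at the first non-rejection). The
  implementation is verified against brute-force enumeration and against
  statsmodels' reference implementation. sigma_p versus rate uses ordinary
  least squares.

## 7. Synthetic data (`synthetic`)

The generator emulates the three observed morphologies; the functional
forms are declared artifacts — only the anchor points and spreads encode
the reported statistics.

* **wet_qs** (0.00625/0.025/0.1 1/s): saturating-exponential toe anchored
  by a low-strain tangent (1.6822/1.7497/3.2378 kPa) plus a power-law
  hardening term pinned to the transition stress (0.1046/0.1069/0.1400 kPa
  at 7.5/7.5/7.2% strain). The two anchors are controlled independently
  because their reported spreads differ by an order of magnitude and a
  single-anchor shape cannot reproduce the published significance pattern
  (tangent modulus separating across rates while sigma_t does not).
* **wet_hr** (50-750 1/s): smoothstep rise to an exact peak at the
  transition anchor, a smooth softening dip (default depth 30%) to 1.5x the
  peak strain, then exponential re-hardening. Peak stress grows linearly
  with rate (15 + 0.045*rate kPa) and peak strain creeps upward with rate —
  declared trends, since no per-rate table of these anchors is published.
* **dry** (0.00625/0.1/250 1/s): linear elastic toe to the yield anchor
  (108.6/138.3/166.4 kPa at 4.19/6.06/7.76% strain) then
  exponential-saturating work hardening whose initial slope (~800 kPa) sits
  well below the elastic slope (~2100-2600 kPa) so the yield point remains
  well defined for offset-yield extraction.

Per-sample jitter draws anchors from normal distributions with SD =
published SE x sqrt(n) (approximating sample SDs), truncated at 20% of the
mean to preserve validity; the truncation only matters for groups whose
reported spread is comparable to the mean. Multiplicative Gaussian noise
(default 2%) is applied pointwise. The default campaign reproduces the
published test matrix (68 samples over 11 rate/condition groups). Gauge
records get additive Gaussian noise at a configured SNR (default 40 dB).

**What passing tests show — and don't.** The seeded campaign reproduces the
qualitative statistical fingerprint of the tissue study: quasi-static wet
tangent modulus differs significantly across rates, every dry metric is
statistically indistinguishable across rates, and the high-rate peak stress
rises linearly with rate. Because the generator *encodes* the published
anchor statistics, these tests validate the analysis pipeline (metric
extraction, ANOVA, Holm-Sidak, trend fitting), not the biology; they say
nothing about whether real tissue satisfies the template forms, and the
measured tissue tables are deliberately not treated as computationally
reproducible outcomes.

## 8. Problem sizes and determinism

Default problem sizes are chosen so the whole suite runs in well under a
minute of CPU: material-point runs use ~12k steps at high rate (one run per
curve), the virtual bar uses ~1500 nodes x ~5000 steps per shot, mixtures
use 1000 subcells on a 121-point strain grid, and calibrations converge in
40-60 simulator evaluations. All randomness flows through explicit integer
seeds (NumPy `default_rng` / `SeedSequence.spawn`); identical configs and
seeds give byte-identical pipeline outputs, which the manifest checksums
make verifiable.

## 9. Known limitations

* 1-D throughout: no radial inertia, friction, or Pochhammer-Chree
  dispersion in the bar model; no 3-D stress redistribution in the mixture.
* Bars are elastic; real polycarbonate bars are viscoelastic and their
  signals need a propagation correction that is out of scope here.
* The lumped specimen has no mass, so specimen inertia (a real contributor
  to early-time non-equilibrium in soft tissue) appears only through the
  ringing of the bar coupling, not as a material effect.
* The mixture rule is quasi-static; water's inertial strengthening at high
  rates is not represented in the sweep.
* Isothermal, no damage or failure, compression only.
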