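"""Internal-state-variable viscoplasticity for dry brain tissue and a water EOS.

This module implements a finite-strain ISV viscoplasticity model (the
MSU TP 1.1 family of thermoplastic-type models) reduced to uniaxial,
true-strain-rate-controlled compression, together with the Hugoniot form of
the Mie-Gruneisen equation of state used for liquid water.

Model summary (uniaxial material point)
---------------------------------------
The deformation gradient is split multiplicatively, ``F = Fe Fp``, with the
elastic law written on the logarithmic elastic strain ``Ee = ln(Ue)``::

    M = 2 mu Ee + (K - 2 mu / 3) tr(Ee) I          (Mandel stress)

Plastic flow is driven by an equivalent shear stress built from the Mandel
stress minus a kinematic back stress ``alpha``::

    tau    = f ||dev(M - alpha)||                  (f = 1/2 by default)
    pi     = -tr(M) / 3                            (compression positive)
    gdot_p = gdot0p * sinh(< tau - (k1 + k2 + a_p pi) > / Y) ** m

with the Macaulay bracket ``<x> = max(x, 0)``.  Two scalar internal strains
``xi1`` (chain resistance to slip) and ``xi2`` (large-strain
crystallization-like hardening) evolve with the plastic shear rate, and the
stretch-like tensor ``beta`` feeds an eight-chain back stress with
inverse-Langevin locking at the network locking stretch ``lambda_L``::

    xi1'  = h0 (1 - xi1/xi*)  gdot_p       k1 = C_k1 xi1
    xi*'  = g0 (1 - xi*/xi*_sat) gdot_p
    xi2'  = h1 (lam_p - 1)(1 - xi2/xi2_sat) gdot_p,  k2 = C_k2 xi2
    beta' = Rs1 (Dp beta + beta Dp),       beta(0) = I

Stresses are MPa internally; reported stress-strain curves are in kPa with
compression taken positive.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "MaterialConstants",
    "MaterialState",
    "WaterEOSParams",
    "StressStrainCurve",
    "DRY_BRAIN",
    "WATER",
    "LockingError",
    "IntegrationError",
    "mandel_stress",
    "equivalent_stress_invariants",
    "plastic_shear_rate",
    "back_stress",
    "inverse_langevin",
    "update_isvs",
    "simulate_uniaxial",
    "water_axial_stress",
    "elastic_modulus",
]

_I3 = np.eye(3)


class LockingError(ValueError):
    """Chain stretch reached the network locking stretch; back stress diverges."""


class IntegrationError(RuntimeError):
    """Material-point integration failed (carries the failing step index)."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaterialConstants:
    """Constants of the ISV viscoplasticity model (dry brain defaults).

    Stresses in MPa, rates in 1/s, everything else dimensionless.
    """

    shear_modulus: float = 0.80        # mu
    bulk_modulus: float = 399.73       # K
    ref_shear_rate: float = 120_000.0  # gdot0p
    rate_sensitivity: float = 0.90     # m
    yield_stress: float = 9.00         # Y
    pressure_sensitivity: float = 0.0  # alpha_p
    locking_stretch: float = 2.00      # lambda_L
    rubbery_modulus: float = 0.07      # mu_R
    beta_hardening: float = 1.4        # Rs1
    h0: float = 0.41
    g0: float = 0.3
    h1: float = 0.0
    xi1_init: float = 0.0045
    xistar_init: float = 1.2
    xistar_sat: float = 0.001
    xi2_init: float = 0.0
    xi2_sat: float = 0.4
    c_kappa1: float = 0.41             # MPa
    c_kappa2: float = 0.0              # MPa

    def __post_init__(self):
        positive = {
            "shear_modulus": self.shear_modulus,
            "bulk_modulus": self.bulk_modulus,
            "ref_shear_rate": self.ref_shear_rate,
            "rate_sensitivity": self.rate_sensitivity,
            "yield_stress": self.yield_stress,
            "xistar_sat": self.xistar_sat,
            "xi2_sat": self.xi2_sat,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")
        if not self.locking_stretch > 1:
            raise ValueError("locking_stretch must be > 1")
        for name in ("rubbery_modulus", "xi1_init", "xistar_init", "xi2_init",
                     "h0", "g0", "h1", "c_kappa1", "c_kappa2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **changes) -> "MaterialConstants":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "MaterialConstants":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown material constant(s): {sorted(unknown)}")
        return cls(**data)


#: Dry-brain constants of the calibrated material-point model.
DRY_BRAIN = MaterialConstants()


@dataclass(frozen=True)
class WaterEOSParams:
    """Hugoniot (Us = c0 + s Up) Mie-Gruneisen parameters for water."""

    rho0: float = 1000.0   # kg/m^3
    c0: float = 1480.0     # m/s
    s: float = 1.979       # slope of the Us-Up fit
    gamma0: float = 0.11   # Gruneisen coefficient

    def __post_init__(self):
        if not self.rho0 > 0:
            raise ValueError("rho0 must be > 0")
        if not self.c0 > 0:
            raise ValueError("c0 must be > 0")
        if self.s < 0 or self.gamma0 < 0:
            raise ValueError("s and gamma0 must be >= 0")


#: Standard-condition water Hugoniot parameters.
WATER = WaterEOSParams()


@dataclass
class MaterialState:
    """Kinematic state and internal state variables of the material point.

    Stretches are principal (axial/lateral) values of the axisymmetric
    elastic/plastic deformation; ``beta`` is the full 3x3 stretch-like ISV
    tensor.
    """

    elastic_stretch_axial: float = 1.0
    elastic_stretch_lateral: float = 1.0
    plastic_stretch_axial: float = 1.0
    plastic_stretch_lateral: float = 1.0
    xi1: float = 0.0045
    xistar: float = 1.2
    xi2: float = 0.0
    beta: np.ndarray = field(default_factory=lambda: _I3.copy())
    gamma_p: float = 0.0
    time: float = 0.0

    @classmethod
    def initial(cls, consts: MaterialConstants) -> "MaterialState":
        return cls(xi1=consts.xi1_init, xistar=consts.xistar_init,
                   xi2=consts.xi2_init)

    @property
    def det_fp(self) -> float:
        return self.plastic_stretch_axial * self.plastic_stretch_lateral ** 2

    @property
    def kappa1(self) -> float:
        # linear conjugate, kappa1 = C_k1 * xi1 -- set lazily by callers that
        # know the constants; kept as a helper on the pair below
        raise AttributeError("use conjugate_stresses(state, consts)")


def conjugate_stresses(state: MaterialState,
                       consts: MaterialConstants) -> tuple[float, float]:
    """Stress-like conjugates (kappa1, kappa2) of (xi1, xi2), in MPa."""
    return consts.c_kappa1 * state.xi1, consts.c_kappa2 * state.xi2


@dataclass
class StressStrainCurve:
    """Sampled true-strain / true-stress history, compression positive.

    ``true_stress`` is in kPa, matching the reporting convention of the
    experimental summaries this package emulates.
    """

    true_strain: np.ndarray
    true_stress: np.ndarray
    nominal_rate: float
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.true_strain = np.asarray(self.true_strain, dtype=float)
        self.true_stress = np.asarray(self.true_stress, dtype=float)
        if self.true_strain.ndim != 1 or self.true_stress.ndim != 1:
            raise ValueError("strain and stress must be 1-D arrays")
        if self.true_strain.size != self.true_stress.size:
            raise ValueError("strain and stress must have equal length")
        if self.true_strain.size >= 2 and np.any(np.diff(self.true_strain) <= 0):
            raise ValueError("true_strain must be strictly increasing")

    def __len__(self) -> int:
        return self.true_strain.size

    def stress_at(self, strain) -> np.ndarray:
        """Linear interpolation of stress (kPa) at the given strain(s)."""
        return np.interp(strain, self.true_strain, self.true_stress)


# ---------------------------------------------------------------------------
# elementary operations (general symmetric-tensor form)
# ---------------------------------------------------------------------------


def _require_symmetric(t: np.ndarray, name: str) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.shape != (3, 3):
        raise ValueError(f"{name} must be a 3x3 tensor, got shape {t.shape}")
    if not np.allclose(t, t.T, atol=1e-12 * max(1.0, float(np.abs(t).max()))):
        raise ValueError(f"{name} must be symmetric")
    return t


def _dev(t: np.ndarray) -> np.ndarray:
    return t - (np.trace(t) / 3.0) * _I3


def mandel_stress(Ee: np.ndarray, consts: MaterialConstants) -> np.ndarray:
    """Mandel stress ``M = 2 mu Ee + (K - 2 mu/3) tr(Ee) I`` (MPa)."""
    Ee = _require_symmetric(Ee, "Ee")
    mu, K = consts.shear_modulus, consts.bulk_modulus
    return 2.0 * mu * Ee + (K - 2.0 * mu / 3.0) * np.trace(Ee) * _I3


def equivalent_stress_invariants(M: np.ndarray,
                                 alpha: np.ndarray | None = None,
                                 factor: float = 0.5) -> tuple[float, float]:
    """Equivalent shear stress and compression-positive pressure.

    ``tau = factor * ||dev(M - alpha)||_F`` and ``pi = -tr(M)/3``.  The
    default prefactor 1/2 follows the printed model equations; pass
    ``factor=1/sqrt(2)`` for the alternative convention of the source
    constitutive-model literature.
    """
    M = _require_symmetric(M, "M")
    if alpha is None:
        xi = M
    else:
        alpha = _require_symmetric(alpha, "alpha")
        xi = M - alpha
    tau = factor * float(np.linalg.norm(_dev(xi)))
    pi = -float(np.trace(M)) / 3.0
    return tau, pi


def plastic_shear_rate(tau: float, kappa1: float, kappa2: float,
                       pressure: float, consts: MaterialConstants) -> float:
    """Viscous shear strain rate of the sinh flow law (1/s, never negative)."""
    drive = tau - (kappa1 + kappa2 + consts.pressure_sensitivity * pressure)
    if drive <= 0.0:
        return 0.0
    return consts.ref_shear_rate * math.sinh(drive / consts.yield_stress) ** consts.rate_sensitivity


def inverse_langevin(x: float) -> float:
    """Cohen/Pade approximant ``x (3 - x^2) / (1 - x^2)`` of the inverse
    Langevin function, accurate to a few percent on ``|x| < 1``."""
    if abs(x) >= 1.0:
        raise ValueError("inverse Langevin argument must satisfy |x| < 1")
    return x * (3.0 - x * x) / (1.0 - x * x)


def back_stress(beta: np.ndarray, consts: MaterialConstants) -> np.ndarray:
    """Eight-chain deviatoric back stress from the stretch-like ISV ``beta``.

    The effective chain stretch is ``lam_c = sqrt(tr(beta)/3)``; the back
    stress vanishes for ``beta = I`` and diverges as ``lam_c`` approaches the
    locking stretch, where a :class:`LockingError` is raised.
    """
    beta = _require_symmetric(beta, "beta")
    if np.any(np.linalg.eigvalsh(beta) <= 0):
        raise ValueError("beta must be positive-definite")
    mu_r, lam_l = consts.rubbery_modulus, consts.locking_stretch
    if mu_r == 0.0:
        return np.zeros((3, 3))
    lam_c = math.sqrt(float(np.trace(beta)) / 3.0)
    if lam_c >= lam_l:
        raise LockingError(
            f"chain stretch {lam_c:.4f} reached locking stretch {lam_l:.4f}")
    prefactor = (mu_r / 3.0) * (lam_l / lam_c) * inverse_langevin(lam_c / lam_l)
    return prefactor * _dev(beta)


def _exp_relax(value: float, target: float, modulus: float, dgamma: float,
               scale: float) -> float:
    """Exact step of ``y' = modulus (1 - y/scale) gdot`` toward saturation.

    Integrates the linear ODE over a plastic-shear increment ``dgamma`` with
    frozen coefficients; unconditionally stable and exact in the limit of an
    explicit Euler step for small increments.
    """
    if modulus == 0.0 or dgamma == 0.0:
        return value
    return target + (value - target) * math.exp(-modulus * dgamma / scale)


def update_isvs(state: MaterialState, gamma_dot_p: float, Dp: np.ndarray,
                dt: float, consts: MaterialConstants,
                lambda_p_rule: str = "rms") -> MaterialState:
    """Advance the internal state variables by one explicit step.

    ``Dp`` is the (symmetric, traceless) plastic rate of deformation.  The
    scalar ISVs use exact exponential relaxation toward their saturation
    values with coefficients frozen over the step; ``beta`` uses the exact
    symmetric update ``beta <- exp(Rs1 Dp dt) beta exp(Rs1 Dp dt)`` and the
    plastic stretches follow the diagonal of ``Dp`` (axisymmetric flow).

    ``lambda_p_rule`` selects the effective plastic stretch entering the xi2
    evolution: ``"rms"`` uses ``sqrt(tr(Bp)/3)`` (equal to 1 at zero plastic
    strain); ``"literal"`` uses ``tr(Bp)/3``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    Dp = _require_symmetric(Dp, "Dp")
    if lambda_p_rule not in ("rms", "literal"):
        raise ValueError("lambda_p_rule must be 'rms' or 'literal'")

    new = dataclasses.replace(state, beta=state.beta.copy())
    new.time = state.time + dt
    dgam = gamma_dot_p * dt
    if dgam == 0.0:
        return new

    tr_bp = (state.plastic_stretch_axial ** 2
             + 2.0 * state.plastic_stretch_lateral ** 2)
    lam_p = tr_bp / 3.0
    if lambda_p_rule == "rms":
        lam_p = math.sqrt(lam_p)

    new.xi1 = _exp_relax(state.xi1, state.xistar, consts.h0, dgam, state.xistar)
    new.xistar = _exp_relax(state.xistar, consts.xistar_sat, consts.g0, dgam,
                            consts.xistar_sat)
    new.xi2 = _exp_relax(state.xi2, consts.xi2_sat,
                         consts.h1 * (lam_p - 1.0), dgam, consts.xi2_sat)

    rs1 = consts.beta_hardening
    if np.allclose(Dp, np.diag(np.diagonal(Dp))):
        e = np.exp(rs1 * np.diagonal(Dp) * dt)
        new.beta = state.beta * np.outer(e, e)
    else:  # pragma: no cover - general path, exercised directly in tests
        from scipy.linalg import expm

        E = expm(rs1 * Dp * dt)
        new.beta = E @ state.beta @ E.T

    d_ax, d_lat = float(Dp[0, 0]), float(Dp[1, 1])
    new.plastic_stretch_axial = state.plastic_stretch_axial * math.exp(d_ax * dt)
    new.plastic_stretch_lateral = (state.plastic_stretch_lateral
                                   * math.exp(d_lat * dt))
    new.gamma_p = state.gamma_p + dgam
    return new


# ---------------------------------------------------------------------------
# uniaxial material-point simulator
# ---------------------------------------------------------------------------


def elastic_modulus(consts: MaterialConstants) -> float:
    """Young's modulus ``E = 9 K mu / (3 K + mu)`` of the elastic law (MPa)."""
    mu, K = consts.shear_modulus, consts.bulk_modulus
    return 9.0 * K * mu / (3.0 * K + mu)


def default_time_step(rate: float) -> float:
    """Default integration step: ~2.5e-5 strain per step, clamped to
    [1e-7, 1e-4] s (1e-7 s at 250 1/s and above, 1e-4 s at quasi-static
    rates)."""
    return min(1e-4, max(1e-7, 2.5e-5 / rate))


def simulate_uniaxial(rate: float, max_strain: float, dt: float | None = None,
                      consts: MaterialConstants = DRY_BRAIN,
                      n_output: int = 400,
                      shear_invariant_factor: float = 0.5,
                      flow_rate_factor: float = 0.5,
                      lambda_p_rule: str = "rms",
                      label: str = "dry",
                      record_history: bool = False) -> StressStrainCurve:
    """Integrate the full model in uniaxial-stress compression.

    The axial true strain grows at the constant ``rate`` (compression
    positive); each step applies an elastic predictor with the lateral
    stretch chosen so the lateral stress vanishes exactly (the Hencky-strain
    elastic law makes that a closed-form linear solve), then a plastic
    corrector that evolves the ISVs with the current driving stress.

    Returns a compression-positive :class:`StressStrainCurve` in kPa with
    ``meta`` carrying the final :class:`MaterialState` and integration
    diagnostics; with ``record_history=True`` the meta also carries per-sample
    traces of the plastic shear rate, accumulated plastic shear, det(Fp) and
    the ISVs.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if not 0.0 < max_strain < 1.0:
        raise ValueError("max_strain must lie in (0, 1)")
    if dt is None:
        dt = default_time_step(rate)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if lambda_p_rule not in ("rms", "literal"):
        raise ValueError("lambda_p_rule must be 'rms' or 'literal'")

    mu, K = consts.shear_modulus, consts.bulk_modulus
    mod_lambda = K - 2.0 * mu / 3.0
    # lateral elastic log strain per unit axial elastic log strain (M_lat = 0)
    poisson_ratio = (3.0 * K - 2.0 * mu) / (2.0 * (3.0 * K + mu))
    gdot0, m_exp, Y = consts.ref_shear_rate, consts.rate_sensitivity, consts.yield_stress
    alpha_p = consts.pressure_sensitivity
    mu_r, lam_l, rs1 = consts.rubbery_modulus, consts.locking_stretch, consts.beta_hardening
    ck1, ck2 = consts.c_kappa1, consts.c_kappa2
    h0, g0c, h1 = consts.h0, consts.g0, consts.h1
    xistar_sat, xi2_sat = consts.xistar_sat, consts.xi2_sat
    f_tau, f_dp = shear_invariant_factor, flow_rate_factor

    n_steps = max(1, math.ceil(max_strain / (rate * dt)))
    sample_every = max(1, n_steps // max(2, n_output))

    # state scalars (axisymmetric diagonal kinematics)
    lpa, lpl = 1.0, 1.0            # plastic stretches
    ba, bl = 1.0, 1.0              # beta principal values
    xi1, xistar, xi2 = consts.xi1_init, consts.xistar_init, consts.xi2_init
    gamma_p = 0.0

    strains = [0.0]
    stresses = [0.0]
    if record_history:
        hist = {"gamma_dot_p": [0.0], "gamma_p": [0.0], "det_fp": [1.0],
                "xi1": [xi1], "xistar": [xistar], "xi2": [xi2],
                "chain_stretch": [1.0], "time": [0.0]}

    exp, sinh, sqrt, log = math.exp, math.sinh, math.sqrt, math.log
    last_e_a = 0.0
    for step in range(1, n_steps + 1):
        eps = min(rate * step * dt, max_strain)
        # elastic predictor: axial stretch prescribed, lateral stress-free
        e_a = -eps - log(lpa)                     # axial elastic log strain
        e_l = -poisson_ratio * e_a                # lateral elastic log strain
        tr_e = e_a + 2.0 * e_l
        m_a = 2.0 * mu * e_a + mod_lambda * tr_e  # lateral Mandel stress is 0

        # back stress from beta (deviatoric, diagonal)
        if mu_r > 0.0:
            tr_b = ba + 2.0 * bl
            lam_c = sqrt(tr_b / 3.0)
            if lam_c >= lam_l:
                raise IntegrationError(
                    f"network locking at step {step} (chain stretch "
                    f"{lam_c:.4f} >= {lam_l})", step=step)
            x = lam_c / lam_l
            pref = (mu_r / 3.0) * (lam_l / lam_c) * (x * (3.0 - x * x) / (1.0 - x * x))
            a_ax = pref * (ba - tr_b / 3.0)
            a_lat = pref * (bl - tr_b / 3.0)
        else:
            a_ax = a_lat = 0.0

        # deviator of (M - alpha); tr(M - alpha) = m_a since alpha is deviatoric
        d_ax = (2.0 / 3.0) * m_a - a_ax
        d_lat = -a_lat - m_a / 3.0
        norm = sqrt(d_ax * d_ax + 2.0 * d_lat * d_lat)
        tau = f_tau * norm
        pi = -m_a / 3.0

        drive = tau - (ck1 * xi1 + ck2 * xi2 + alpha_p * pi)
        if drive > 0.0 and norm > 0.0:
            gdot = gdot0 * sinh(drive / Y) ** m_exp
            dp_ax = f_dp * gdot * d_ax / norm
            dp_lat = f_dp * gdot * d_lat / norm
            dgam = gdot * dt
            # ISV updates (exact exponential relaxation, frozen coefficients)
            tr_bp = lpa * lpa + 2.0 * lpl * lpl
            lam_p = tr_bp / 3.0
            if lambda_p_rule == "rms":
                lam_p = sqrt(lam_p)
            xi1 = xistar + (xi1 - xistar) * exp(-h0 * dgam / xistar)
            xistar = xistar_sat + (xistar - xistar_sat) * exp(-g0c * dgam / xistar_sat)
            hc = h1 * (lam_p - 1.0)
            if hc != 0.0:
                xi2 = xi2_sat + (xi2 - xi2_sat) * exp(-hc * dgam / xi2_sat)
            ba *= exp(2.0 * rs1 * dp_ax * dt)
            bl *= exp(2.0 * rs1 * dp_lat * dt)
            lpa *= exp(dp_ax * dt)
            lpl *= exp(dp_lat * dt)
            gamma_p += dgam
        else:
            gdot = 0.0

        last_e_a = e_a
        if step % sample_every == 0 or step == n_steps:
            # Cauchy stress = Mandel / Je in the principal frame
            je = exp(e_a + 2.0 * e_l)
            sigma = -m_a / je
            if not math.isfinite(sigma):
                raise IntegrationError(
                    f"non-finite stress at step {step}", step=step)
            strains.append(eps)
            stresses.append(sigma * 1e3)  # MPa -> kPa
            if record_history:
                hist["gamma_dot_p"].append(gdot)
                hist["gamma_p"].append(gamma_p)
                hist["det_fp"].append(lpa * lpl * lpl)
                hist["xi1"].append(xi1)
                hist["xistar"].append(xistar)
                hist["xi2"].append(xi2)
                hist["chain_stretch"].append(sqrt((ba + 2.0 * bl) / 3.0))
                hist["time"].append(step * dt)

    final_state = MaterialState(
        elastic_stretch_axial=math.exp(last_e_a),
        elastic_stretch_lateral=math.exp(-poisson_ratio * last_e_a),
        plastic_stretch_axial=lpa, plastic_stretch_lateral=lpl,
        xi1=xi1, xistar=xistar, xi2=xi2,
        beta=np.diag([ba, bl, bl]), gamma_p=gamma_p, time=n_steps * dt)

    meta = {"dt": dt, "n_steps": n_steps, "final_state": final_state,
            "det_fp": lpa * lpl * lpl, "consts": consts}
    if record_history:
        meta["history"] = {k: np.asarray(v) for k, v in hist.items()}
    # drop duplicate strain samples (can occur when max_strain caps the ramp)
    strains_arr = np.asarray(strains)
    keep = np.concatenate([[True], np.diff(strains_arr) > 0])
    return StressStrainCurve(strains_arr[keep], np.asarray(stresses)[keep],
                             nominal_rate=rate, label=label, meta=meta)


# ---------------------------------------------------------------------------
# water equation of state
# ---------------------------------------------------------------------------


def water_axial_stress(eta: float, eos: WaterEOSParams = WATER) -> float:
    """Compression-positive pressure of water at volumetric compression
    ``eta = 1 - rho0/rho`` (MPa), Hugoniot-form Mie-Gruneisen::

        p = rho0 c0^2 eta / (1 - s eta)^2 * (1 - gamma0 eta / 2)

    Water carries no deviatoric strength, so this is also the axial stress of
    a fully confined (uniaxial-strain) water column.
    """
    eta = float(eta)
    if eta < 0.0:
        raise ValueError("volumetric compression eta must be >= 0")
    if eos.s > 0 and eta >= 1.0 / eos.s:
        raise ValueError(
            f"eta={eta:.4f} at or beyond the densification singularity "
            f"1/s={1.0 / eos.s:.4f}")
    p_pa = (eos.rho0 * eos.c0 ** 2 * eta / (1.0 - eos.s * eta) ** 2
            * (1.0 - eos.gamma0 * eta / 2.0))
    return p_pa / 1e6
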