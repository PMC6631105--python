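"""Least-squares calibration of the material-point model to stress-strain data.

The optimizer is bounded Nelder-Mead on log-scaled parameters: the simulator
is smooth but not analytically differentiable in its constants, the free
parameters are strictly positive and span decades, and derivative-free
simplex search is robust to the mild integration noise of the explicit
stepper.  The loss is the sum of squared stress misfits (kPa^2) on each
target curve's strain grid, with a relative (per-point normalized) variant
for unit-free fitting.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

from .constitutive import (DRY_BRAIN, MaterialConstants, StressStrainCurve,
                           simulate_uniaxial)

__all__ = ["FitSpec", "FitResult", "residual", "fit_constants",
           "IdentifiabilityError"]

#: Parameter pairs that a single uniaxial curve cannot separate; they are
#: rejected from a joint free set unless explicitly allowed.
_DEGENERATE_PAIRS = (("c_kappa1", "h0"), ("shear_modulus", "bulk_modulus"))


class IdentifiabilityError(ValueError):
    """The requested free set is not identifiable from the target data."""


@dataclass
class FitSpec:
    """Specification of one calibration run."""

    free_names: Sequence[str]
    bounds: dict                          # name -> (lo, hi), finite, ordered
    fixed: MaterialConstants = DRY_BRAIN
    curves: Sequence[StressStrainCurve] = ()
    initial: dict = field(default_factory=dict)   # name -> starting value
    loss: str = "sse"                     # "sse" | "relative-sse"
    seed: int = 0
    max_evals: int = 400
    rel_tol: float = 1e-8
    dt: float | None = None               # passed through to the simulator
    allow_degenerate: bool = False

    def __post_init__(self):
        self.free_names = tuple(self.free_names)
        valid = {f.name for f in dataclasses.fields(MaterialConstants)}
        unknown = set(self.free_names) - valid
        if unknown:
            raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")
        if self.loss not in ("sse", "relative-sse"):
            raise ValueError("loss must be 'sse' or 'relative-sse'")
        for name in self.free_names:
            lo, hi = self.bounds[name]
            if not (math.isfinite(lo) and math.isfinite(hi) and 0 < lo < hi):
                raise ValueError(f"bounds for {name} must be finite, positive "
                                 f"and ordered")
        if not self.allow_degenerate:
            free = set(self.free_names)
            for pair in _DEGENERATE_PAIRS:
                if free.issuperset(pair):
                    raise IdentifiabilityError(
                        f"jointly freeing {pair} is ill-posed from uniaxial "
                        f"curves; fix one or set allow_degenerate=True")


@dataclass
class FitResult:
    """Outcome of a calibration run."""

    constants: MaterialConstants
    loss: float
    n_iterations: int
    n_evaluations: int
    converged: bool
    residual_traces: list           # per-curve (strain, stress residual kPa)
    free_names: tuple
    fitted_values: dict

    def report(self) -> str:
        lines = [f"calibration: {'converged' if self.converged else 'NOT converged'}",
                 f"loss = {self.loss:.6g} ({self.n_evaluations} evaluations)"]
        for name, value in self.fitted_values.items():
            lines.append(f"  {name} = {value:.6g}")
        return "\n".join(lines)


def _simulate_for_curve(consts: MaterialConstants, curve: StressStrainCurve,
                        dt: float | None) -> np.ndarray:
    model = simulate_uniaxial(curve.nominal_rate,
                              float(curve.true_strain.max()) * 1.001,
                              dt=dt, consts=consts, n_output=1500)
    # cubic interpolation of the densely sampled model keeps the grid
    # mismatch error far below any physical misfit
    spline = CubicSpline(model.true_strain, model.true_stress)
    return spline(curve.true_strain)


def residual(consts: MaterialConstants, curves: Sequence[StressStrainCurve],
             loss: str = "sse", dt: float | None = None) -> float:
    """Sum over curves of squared stress misfit (kPa^2; unitless for
    relative loss) on each curve's strain grid."""
    total = 0.0
    for curve in curves:
        try:
            model = _simulate_for_curve(consts, curve, dt)
        except Exception as exc:
            raise RuntimeError(
                f"simulation failed at rate {curve.nominal_rate} 1/s") from exc
        diff = model - curve.true_stress
        if loss == "relative-sse":
            scale = max(float(np.abs(curve.true_stress).max()), 1e-12)
            diff = diff / scale
        total += float(np.dot(diff, diff))
    return total


def fit_constants(spec: FitSpec) -> FitResult:
    """Bounded local least-squares fit of the free constants.

    Deterministic given the spec (Nelder-Mead has no internal randomness;
    the seed is recorded for provenance).  Convergence requires the relative
    simplex loss change to fall below ``spec.rel_tol``.
    """
    if spec.free_names and not spec.curves:
        raise ValueError("at least one target curve is required")
    if "rate_sensitivity" in spec.free_names:
        rates = {float(c.nominal_rate) for c in spec.curves}
        if len(rates) < 2:
            raise IdentifiabilityError(
                "freeing rate_sensitivity requires curves at >= 2 distinct "
                "strain rates")

    if not spec.free_names:
        base_loss = residual(spec.fixed, spec.curves, spec.loss, spec.dt) \
            if spec.curves else 0.0
        return FitResult(constants=spec.fixed, loss=base_loss, n_iterations=0,
                         n_evaluations=0, converged=True,
                         residual_traces=_traces(spec.fixed, spec),
                         free_names=(), fitted_values={})

    names = spec.free_names
    x0 = np.array([math.log(spec.initial.get(
        name, getattr(spec.fixed, name))) for name in names])
    log_bounds = [(math.log(spec.bounds[n][0]), math.log(spec.bounds[n][1]))
                  for n in names]
    for xi, (lo, hi), name in zip(x0, log_bounds, names):
        if not lo <= xi <= hi:
            raise ValueError(f"initial value for {name} violates its bounds")

    def objective(x):
        consts = spec.fixed.replace(
            **{n: math.exp(v) for n, v in zip(names, x)})
        return residual(consts, spec.curves, spec.loss, spec.dt)

    result = minimize(objective, x0, method="Nelder-Mead", bounds=log_bounds,
                      options={"maxfev": spec.max_evals,
                               "fatol": spec.rel_tol * max(objective(x0), 1e-30),
                               "xatol": 1e-6, "adaptive": len(names) > 2})
    fitted = {n: math.exp(v) for n, v in zip(names, result.x)}
    constants = spec.fixed.replace(**fitted)
    return FitResult(constants=constants, loss=float(result.fun),
                     n_iterations=int(result.nit),
                     n_evaluations=int(result.nfev),
                     converged=bool(result.success),
                     residual_traces=_traces(constants, spec),
                     free_names=tuple(names), fitted_values=fitted)


def _traces(consts: MaterialConstants, spec: FitSpec) -> list:
    traces = []
    for curve in spec.curves:
        model = _simulate_for_curve(consts, curve, spec.dt)
        traces.append((curve.true_strain.copy(), model - curve.true_stress))
    return traces
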