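"""Water / dry-brain mixture homogenization at desk scale.

Replaces the full 3-D explicit-FE mixture study with subcell averaging:
``n`` equal-volume subcells are randomly assigned water or dry-brain
behavior at a target water mass fraction, and the specimen-average stress is
computed by iso-strain (Voigt) averaging, with an iso-stress (Reuss)
alternative behind the same signature.

The water subcell has no deviatoric strength.  Under the common-axial-strain
assumption with laterally unconstrained subcells, a pressure-only material
supports no axial stress (it bulges at constant volume), so the default
water axial response is zero; the ``lateral_confinement`` knob interpolates
toward the fully confined uniaxial-strain limit where the axial stress is
the Mie-Gruneisen EOS pressure at the full volumetric compression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .constitutive import (DRY_BRAIN, WATER, MaterialConstants, StressStrainCurve,
                           WaterEOSParams, simulate_uniaxial, water_axial_stress)

__all__ = [
    "PhaseAssignment",
    "MixtureResult",
    "mass_to_volume_fraction",
    "assign_phases",
    "homogenize_isostrain",
    "mixture_sweep",
    "water_subcell_model",
    "dry_brain_subcell_model",
    "DEFAULT_FRACTIONS",
    "RHO_WATER",
    "RHO_DRY_BRAIN",
]

RHO_WATER = 1000.0      # kg/m^3
RHO_DRY_BRAIN = 1200.0  # kg/m^3, declared default (not a measured value)

#: Water mass fractions of the four default simulation cases (20-80% m/m).
DEFAULT_FRACTIONS = (0.2, 0.4, 0.6, 0.8)


def mass_to_volume_fraction(water_mass_fraction: float,
                            rho_water: float = RHO_WATER,
                            rho_dry: float = RHO_DRY_BRAIN) -> float:
    """Convert a water mass fraction to a volume fraction,
    ``v = (w/rho_w) / (w/rho_w + (1-w)/rho_d)``."""
    w = float(water_mass_fraction)
    if not 0.0 <= w <= 1.0:
        raise ValueError("mass fraction must lie in [0, 1]")
    if rho_water <= 0 or rho_dry <= 0:
        raise ValueError("densities must be > 0")
    vw = w / rho_water
    return vw / (vw + (1.0 - w) / rho_dry)


@dataclass
class PhaseAssignment:
    """Random water/dry labelling of equal-volume subcells."""

    n_subcells: int
    labels: np.ndarray                  # array of "water" / "dry"
    water_mass_fraction: float
    water_volume_fraction: float        # realized
    seed: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.size != self.n_subcells:
            raise ValueError("labels length must equal n_subcells")

    @property
    def n_water(self) -> int:
        return int(np.sum(self.labels == "water"))


def assign_phases(n: int, water_mass_fraction: float,
                  rho_water: float = RHO_WATER, rho_dry: float = RHO_DRY_BRAIN,
                  seed: int = 0) -> PhaseAssignment:
    """Randomly assign ``n`` subcells to water/dry at the target fraction.

    The realized volume fraction is the nearest integer count, hence within
    1/n of the converted target; the permutation is reproducible under the
    seed.
    """
    if n < 10:
        raise ValueError("need at least 10 subcells for a meaningful mixture")
    v_target = mass_to_volume_fraction(water_mass_fraction, rho_water, rho_dry)
    n_water = round(v_target * n)
    labels = np.array(["dry"] * n, dtype=object)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_water, replace=False)
    labels[idx] = "water"
    return PhaseAssignment(n_subcells=n, labels=labels,
                           water_mass_fraction=water_mass_fraction,
                           water_volume_fraction=n_water / n, seed=seed)


def water_subcell_model(eos: WaterEOSParams = WATER,
                        lateral_confinement: float = 0.0
                        ) -> Callable[[np.ndarray], np.ndarray]:
    """Axial stress (kPa) of a water subcell at compressive true strain.

    With ``lateral_confinement = 0`` (default) the subcell bulges freely at
    constant volume and carries no axial stress; with 1 it is fully confined
    (uniaxial strain) and the axial stress is the EOS pressure at volumetric
    compression ``eta = 1 - exp(-strain)``.
    """
    if not 0.0 <= lateral_confinement <= 1.0:
        raise ValueError("lateral_confinement must lie in [0, 1]")

    def model(strain):
        strain = np.asarray(strain, dtype=float)
        eta = lateral_confinement * (1.0 - np.exp(-strain))
        return np.array([water_axial_stress(e, eos) * 1e3 for e in np.atleast_1d(eta)]
                        ).reshape(strain.shape)

    return model


def dry_brain_subcell_model(rate: float, max_strain: float,
                            consts: MaterialConstants = DRY_BRAIN,
                            dt: float | None = None
                            ) -> Callable[[np.ndarray], np.ndarray]:
    """Axial stress (kPa) of a dry-brain subcell: the ISV material-point
    response at the given rate, linearly interpolated on strain."""
    curve = simulate_uniaxial(rate, max_strain, dt=dt, consts=consts)
    return lambda strain: curve.stress_at(strain)


@dataclass
class MixtureResult:
    """Per-fraction homogenized curves with pure-phase bounds."""

    curves: dict                      # water mass fraction -> StressStrainCurve
    pure_dry: StressStrainCurve
    pure_water: StressStrainCurve
    rule: str
    rate: float
    seed: int

    def table(self) -> pd.DataFrame:
        """Tidy (fraction, true_strain, avg_stress_kPa, rule) table."""
        rows = []
        for frac, curve in sorted(self.curves.items()):
            rows.append(pd.DataFrame({
                "fraction": frac,
                "true_strain": curve.true_strain,
                "avg_stress_kPa": curve.true_stress,
                "rule": self.rule,
            }))
        return pd.concat(rows, ignore_index=True)


def _phase_curves(assignment: PhaseAssignment, strain_grid: np.ndarray,
                  water_model, dry_model) -> tuple[np.ndarray, np.ndarray]:
    try:
        s_w = np.asarray(water_model(strain_grid), dtype=float)
    except Exception as exc:
        raise RuntimeError("water phase model failed on the strain grid") from exc
    try:
        s_d = np.asarray(dry_model(strain_grid), dtype=float)
    except Exception as exc:
        raise RuntimeError("dry phase model failed on the strain grid") from exc
    return s_w, s_d


def homogenize_isostrain(assignment: PhaseAssignment,
                         strain_grid: Sequence[float], rate: float,
                         water_model: Callable, dry_model: Callable,
                         rule: str = "voigt") -> StressStrainCurve:
    """Specimen-average stress with every subcell at the common strain.

    ``rule="voigt"`` (iso-strain) averages subcell stresses at equal volume
    weights; ``rule="reuss"`` (iso-stress) averages subcell strains at common
    stress and re-interpolates back onto the strain grid (zero if either
    phase has no strength, as an infinitely compliant branch dominates).
    """
    if rule not in ("voigt", "reuss"):
        raise ValueError("rule must be 'voigt' or 'reuss'")
    strain_grid = np.asarray(strain_grid, dtype=float)
    v_w = assignment.n_water / assignment.n_subcells
    v_d = 1.0 - v_w
    s_w, s_d = _phase_curves(assignment, strain_grid, water_model, dry_model)

    if rule == "voigt":
        avg = v_w * s_w + v_d * s_d
    else:
        # iso-stress: strains add at common stress; invert each monotone
        # stress-strain branch on a shared stress grid
        s_max = min(s_w.max(initial=0.0), s_d.max(initial=0.0))
        if s_max <= 0.0:
            avg = np.zeros_like(strain_grid)
        else:
            stress_grid = np.linspace(0.0, s_max, strain_grid.size)
            e_w = np.interp(stress_grid, s_w, strain_grid)
            e_d = np.interp(stress_grid, s_d, strain_grid)
            e_avg = v_w * e_w + v_d * e_d
            avg = np.interp(strain_grid, e_avg, stress_grid,
                            right=stress_grid[-1])
    return StressStrainCurve(
        strain_grid, avg, nominal_rate=rate, label="mixture",
        meta={"water_mass_fraction": assignment.water_mass_fraction,
              "water_volume_fraction": assignment.water_volume_fraction,
              "rule": rule, "seed": assignment.seed})


def mixture_sweep(fractions: Sequence[float] = DEFAULT_FRACTIONS,
                  rate: float = 250.0, max_strain: float = 0.3,
                  water_model: Callable | None = None,
                  dry_model: Callable | None = None,
                  n_subcells: int = 1000, seed: int = 0,
                  rule: str = "voigt", n_grid: int = 121,
                  rho_water: float = RHO_WATER,
                  rho_dry: float = RHO_DRY_BRAIN) -> MixtureResult:
    """Run the homogenization over a set of water mass fractions.

    Defaults cover the four water fractions 20/40/60/80% m/m at 250 1/s with
    the calibrated dry-brain model and the strength-free water subcell;
    attaches pure-phase bound curves.
    """
    fractions = tuple(float(f) for f in fractions)
    for f in fractions:
        if not 0.0 < f < 1.0:
            raise ValueError("fractions must lie in (0, 1)")
    if water_model is None:
        water_model = water_subcell_model()
    if dry_model is None:
        dry_model = dry_brain_subcell_model(rate, max_strain)
    grid = np.linspace(0.0, max_strain, n_grid)

    curves = {}
    for j, frac in enumerate(fractions):
        assignment = assign_phases(n_subcells, frac, rho_water, rho_dry,
                                   seed=seed + j)
        curves[frac] = homogenize_isostrain(assignment, grid, rate,
                                            water_model, dry_model, rule=rule)
    pure_dry = StressStrainCurve(grid, np.asarray(dry_model(grid), dtype=float),
                                 nominal_rate=rate, label="dry")
    pure_water = StressStrainCurve(grid, np.asarray(water_model(grid), dtype=float),
                                   nominal_rate=rate, label="water")
    return MixtureResult(curves=curves, pure_dry=pure_dry,
                         pure_water=pure_water, rule=rule, rate=rate,
                         seed=seed)
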