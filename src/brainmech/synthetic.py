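"""Synthetic stress-strain datasets and gauge signals for pipeline testing.

Three curve morphologies are generated, matching what wet and lyophilized
(dry) brain tissue show in compression:

* ``wet_qs``  — quasi-static wet brain: concave-up monotone hardening (toe
  region then progressive stiffening), anchored by an elastic-viscoelastic
  transition stress near 0.10-0.14 kPa at ~7.5% strain;
* ``wet_hr``  — high-rate wet brain: an initial hardening peak (sigma_p) at
  the transition strain, a softening dip, then concave-up re-hardening;
* ``dry``     — dry brain: a linear elastic toe up to a yield point
  (transition stress ~110-170 kPa at 4-8% strain) followed by concave-down
  work hardening, with rate-insensitive anchor statistics.

The functional forms (smoothstep rise, exponential-saturating hardening,
smooth softening bump) are declared modelling artifacts; only the anchor
points and their spreads encode the reported tissue statistics.  Per-sample
jitter scales are standard errors times sqrt(n), approximating sample
standard deviations from the published standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .constitutive import StressStrainCurve
from .shpb import GaugeRecordSet, SHPBConfig, simulate_shpb

__all__ = [
    "CurveTemplate",
    "DesignRow",
    "ExperimentalDesign",
    "generate_curve",
    "generate_design",
    "generate_gauges",
    "default_template",
    "DEFAULT_DESIGN",
]


@dataclass(frozen=True)
class CurveTemplate:
    """Anchor parameters of one synthetic curve morphology.

    ``transition_stress``/``transition_strain`` place sigma_t (quasi-static)
    or sigma_p / the yield point; ``hardening_coefficient`` (kPa) scales the
    large-strain hardening term; ``softening_depth`` is the post-peak dip as
    a fraction of the peak (high-rate wet only).  For quasi-static wet
    curves the low-strain tangent is anchored separately by ``toe_tangent``
    (a saturating-exponential toe with strain constant ``toe_scale``), since
    the reported tangent-modulus and transition-stress statistics vary
    independently; the transition anchor is honored through the power-law
    hardening term whenever it exceeds the toe contribution there.
    """

    regime: str                     # "wet_qs" | "wet_hr" | "dry"
    rate: float                     # 1/s
    transition_stress: float        # kPa
    transition_strain: float
    hardening_coefficient: float = 40.0    # kPa
    hardening_rate: float = 10.0           # 1/strain
    hardening_exponent: float = 2.0        # wet_qs hardening power
    softening_depth: float = 0.3
    toe_tangent: float = 2.0        # kPa; wet_qs initial tangent scale
    toe_scale: float = 0.02         # strain constant of the wet_qs toe
    noise_sd: float = 0.0           # multiplicative, fraction of stress
    n_points: int = 200
    max_strain: float = 0.30

    def __post_init__(self):
        if self.regime not in ("wet_qs", "wet_hr", "dry"):
            raise ValueError("regime must be 'wet_qs', 'wet_hr' or 'dry'")
        if self.transition_stress <= 0 or self.transition_strain <= 0:
            raise ValueError("transition anchors must be positive")
        if not 0.0 <= self.softening_depth < 1.0:
            raise ValueError("softening_depth must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")
        if not self.transition_strain < self.max_strain:
            raise ValueError("transition_strain must precede max_strain")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _clean_curve(template: CurveTemplate, strain: np.ndarray) -> np.ndarray:
    st, et = template.transition_stress, template.transition_strain
    ch, kh = template.hardening_coefficient, template.hardening_rate
    if template.regime == "wet_qs":
        t_mod, e0 = template.toe_tangent, template.toe_scale
        toe = t_mod * e0 * (1.0 - np.exp(-strain / e0))
        amp = st - t_mod * e0 * (1.0 - math.exp(-et / e0))
        hard = max(amp, 0.0) * (strain / et) ** template.hardening_exponent
        return toe + hard
    if template.regime == "dry":
        slope = st / et               # linear toe ending at the yield point
        work = ch * (1.0 - np.exp(-kh * np.maximum(strain - et, 0.0)))
        return np.where(strain <= et, slope * strain, st + work)
    # wet_hr: rise to the peak, softening dip to 1.5x the peak strain,
    # then concave-up re-hardening
    e_min = 1.5 * et
    rise = st * _smoothstep(strain / et)
    dip = st * template.softening_depth * _smoothstep(
        (strain - et) / (e_min - et))
    harden = ch * (np.exp(kh * np.maximum(strain - e_min, 0.0)) - 1.0)
    return rise - dip + harden


def generate_curve(template: CurveTemplate, seed: int = 0) -> StressStrainCurve:
    """One synthetic curve: the template's clean morphology with
    multiplicative Gaussian noise at ``noise_sd``, reproducible under the
    seed.  The strain grid excludes zero so noisy stresses stay positive
    scale-free."""
    rng = np.random.default_rng(seed)
    strain = np.linspace(0.0, template.max_strain, template.n_points + 1)[1:]
    # keep the transition anchor on the grid so the constructed peak is exact
    strain = np.unique(np.append(strain, template.transition_strain))
    stress = _clean_curve(template, strain)
    if template.noise_sd > 0:
        stress = stress * (1.0 + template.noise_sd
                           * rng.standard_normal(stress.size))
        stress = np.maximum(stress, 0.0)
    label = {"wet_qs": "wet", "wet_hr": "wet", "dry": "dry"}[template.regime]
    return StressStrainCurve(
        strain, stress, nominal_rate=template.rate, label=label,
        meta={"regime": template.regime, "seed": seed,
              "template": template})


# ---------------------------------------------------------------------------
# default templates and jitter scales (anchors from the reported wet/dry
# compression statistics; spreads are SE * sqrt(n))
# ---------------------------------------------------------------------------

# (transition_stress kPa, transition_strain, toe tangent kPa,
#  stress jitter SD kPa, strain jitter SD, tangent jitter SD kPa)
_WET_QS = {
    0.00625: (0.1046, 0.075, 1.6822, 0.0046 * math.sqrt(6),
              0.0040 * math.sqrt(6), 0.0047 * math.sqrt(6)),
    0.025: (0.1069, 0.075, 1.7497, 0.0020 * math.sqrt(7),
            0.0060 * math.sqrt(7), 0.0021 * math.sqrt(7)),
    0.1: (0.1400, 0.072, 3.2378, 0.0377 * 4.0, 0.0050 * 4.0, 0.0371 * 4.0),
}

_DRY = {
    0.00625: (108.602, 0.0419, 17.786 * 2.0, 0.0086 * 2.0),
    0.1: (138.313, 0.0606, 55.902 * math.sqrt(5), 0.0100 * math.sqrt(5)),
    250.0: (166.389, 0.0776, 48.142 * 2.0, 0.0106 * 2.0),
}

# high-rate wet anchors: sigma_p grows linearly with rate and its strain
# creeps up with rate; spreads are declared (no per-rate table is reported)
_WET_HR_SLOPE = 0.045      # kPa per 1/s
_WET_HR_INTERCEPT = 15.0   # kPa
_WET_HR_STRAIN0 = 0.028
_WET_HR_STRAIN_SLOPE = 3.0e-5
_WET_HR_REL_SD = 0.15      # relative SD of sigma_p
_WET_HR_STRAIN_REL_SD = 0.10


def default_template(regime: str, rate: float,
                     noise_sd: float = 0.0) -> CurveTemplate:
    """Template anchored at the reported statistics for (regime, rate)."""
    if regime == "wet_qs":
        if rate not in _WET_QS:
            raise KeyError(f"no quasi-static wet anchors at rate {rate}")
        st, et, t_mod, *_ = _WET_QS[rate]
        return CurveTemplate(regime=regime, rate=rate, transition_stress=st,
                             transition_strain=et, toe_tangent=t_mod,
                             noise_sd=noise_sd, max_strain=0.30)
    if regime == "dry":
        if rate not in _DRY:
            raise KeyError(f"no dry anchors at rate {rate}")
        st, et, *_ = _DRY[rate]
        # work-hardening initial slope (ch * kh ~ 800 kPa) well below the
        # elastic toe slope so the yield point stays well defined
        return CurveTemplate(regime=regime, rate=rate, transition_stress=st,
                             transition_strain=et,
                             hardening_coefficient=400.0, hardening_rate=2.0,
                             noise_sd=noise_sd, max_strain=0.30)
    if regime == "wet_hr":
        st = _WET_HR_INTERCEPT + _WET_HR_SLOPE * rate
        et = min(0.06, _WET_HR_STRAIN0 + _WET_HR_STRAIN_SLOPE * rate)
        return CurveTemplate(regime=regime, rate=rate, transition_stress=st,
                             transition_strain=et, hardening_coefficient=40.0,
                             hardening_rate=10.0, softening_depth=0.3,
                             noise_sd=noise_sd, max_strain=0.30)
    raise ValueError("regime must be 'wet_qs', 'wet_hr' or 'dry'")


@dataclass(frozen=True)
class DesignRow:
    rate: float
    kind: str            # "wet" | "dry"
    n_samples: int

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.kind not in ("wet", "dry"):
            raise ValueError("kind must be 'wet' or 'dry'")

    @property
    def regime(self) -> str:
        if self.kind == "dry":
            return "dry"
        return "wet_hr" if self.rate >= 50.0 else "wet_qs"


@dataclass(frozen=True)
class ExperimentalDesign:
    """Rows of (rate, wet/dry, n_samples) defining a synthetic campaign."""

    rows: tuple

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(self.rows))

    @property
    def total_samples(self) -> int:
        return sum(r.n_samples for r in self.rows)


#: Default design: the full wet + dry test matrix (68 samples).
DEFAULT_DESIGN = ExperimentalDesign(rows=(
    DesignRow(0.00625, "wet", 6),
    DesignRow(0.025, "wet", 7),
    DesignRow(0.1, "wet", 16),
    DesignRow(50.0, "wet", 6),
    DesignRow(250.0, "wet", 4),
    DesignRow(450.0, "wet", 5),
    DesignRow(550.0, "wet", 7),
    DesignRow(750.0, "wet", 4),
    DesignRow(0.00625, "dry", 4),
    DesignRow(0.1, "dry", 5),
    DesignRow(250.0, "dry", 4),
))


def _jitter_template(template: CurveTemplate, rng: np.random.Generator
                     ) -> CurveTemplate:
    """Per-sample template jitter at the tabulated SE*sqrt(n) scales.

    Draws are truncated at 20% of the mean to keep anchors positive (the
    reported spreads of some groups are comparable to their means)."""
    regime, rate = template.regime, template.rate
    toe = template.toe_tangent
    if regime == "wet_qs":
        _, _, t_mod, sd_s, sd_e, sd_t = _WET_QS[rate]
        toe = max(0.2 * t_mod, t_mod + sd_t * rng.standard_normal())
    elif regime == "dry":
        _, _, sd_s, sd_e = _DRY[rate]
    else:
        sd_s = _WET_HR_REL_SD * template.transition_stress
        sd_e = _WET_HR_STRAIN_REL_SD * template.transition_strain
    st = max(0.2 * template.transition_stress,
             template.transition_stress + sd_s * rng.standard_normal())
    et = max(0.2 * template.transition_strain,
             template.transition_strain + sd_e * rng.standard_normal())
    et = min(et, 0.9 * template.max_strain)
    return replace(template, transition_stress=st, transition_strain=et,
                   toe_tangent=toe)


def generate_design(design: ExperimentalDesign = DEFAULT_DESIGN,
                    master_seed: int = 0, noise_sd: float = 0.02,
                    jitter: bool = True
                    ) -> tuple[list, pd.DataFrame]:
    """Generate one curve per sample of the design.

    Returns ``(curves, manifest)`` where the manifest records sample id,
    rate, kind, regime and the per-sample seed.  Sampling is reproducible
    under ``master_seed`` via spawned seed sequences.
    """
    ss = np.random.SeedSequence(master_seed)
    curves: list[StressStrainCurve] = []
    records = []
    sample_id = 0
    for row in design.rows:
        base = default_template(row.regime, row.rate, noise_sd=noise_sd)
        for _ in range(row.n_samples):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            template = _jitter_template(base, rng) if jitter else base
            curve_seed = int(rng.integers(2 ** 31))
            curve = generate_curve(template, seed=curve_seed)
            curve.meta.update(sample_id=sample_id, kind=row.kind)
            curves.append(curve)
            records.append({"sample_id": sample_id, "rate_per_s": row.rate,
                            "kind": row.kind, "regime": row.regime,
                            "seed": curve_seed})
            sample_id += 1
    return curves, pd.DataFrame.from_records(records)


def generate_gauges(config: SHPBConfig,
                    specimen_model: Callable[[float, float], float] | str | None,
                    seed: int = 0, snr_db: float | None = 40.0,
                    **simulate_kwargs) -> GaugeRecordSet:
    """Virtual SHPB gauge signals with additive Gaussian noise at the given
    signal-to-noise ratio (dB, RMS-based); ``snr_db=None`` disables noise."""
    record = simulate_shpb(config, specimen_model, **simulate_kwargs)
    if snr_db is None:
        return record
    rng = np.random.default_rng(seed)
    for name in ("incident_strain", "transmitted_strain"):
        signal = getattr(record, name)
        rms = float(np.sqrt(np.mean(signal ** 2)))
        sd = rms / 10.0 ** (snr_db / 20.0)
        setattr(record, name, signal + sd * rng.standard_normal(signal.size))
    record.diagnostics["snr_db"] = snr_db
    record.diagnostics["noise_seed"] = seed
    return record
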