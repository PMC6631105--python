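"""Curve metrics and rate-dependence statistics for compression tests.

Metrics follow the conventions of high-rate soft-tissue testing:

* tangent modulus — local slope of the true stress-strain curve, evaluated
  by a symmetric central difference at a target strain (default 5%, with 1%
  also common for quasi-static wet tissue);
* transition stress — at high rate, the initial hardening peak stress
  ``sigma_p`` (first interior local maximum, marking the elastic-inelastic
  transition); at quasi-static rates, the elastic-viscoelastic transition
  stress ``sigma_t``, operationalized as the stress at 5% true strain;
* group statistics — one-way ANOVA over strain-rate groups with step-down
  Holm-Sidak post-hoc pairwise comparisons at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constitutive import StressStrainCurve

__all__ = [
    "CurveMetrics",
    "GroupComparison",
    "TransitionNotFoundError",
    "tangent_modulus",
    "find_transition",
    "extract_metrics",
    "one_way_anova",
    "holm_sidak",
    "compare_groups",
    "rate_dependence_summary",
    "HIGH_RATE_THRESHOLD",
]

#: Strain rates at or above this value (1/s) are treated as high rate.
HIGH_RATE_THRESHOLD = 50.0


class TransitionNotFoundError(ValueError):
    """A high-rate curve has no admissible interior stress maximum."""


@dataclass
class CurveMetrics:
    """Summary metrics of one stress-strain curve (stresses in kPa)."""

    tangent_modulus: float
    transition_stress: float
    transition_strain: float
    regime: str                     # "quasi_static" | "high_rate"
    rate: float

    def __post_init__(self):
        if self.regime not in ("quasi_static", "high_rate"):
            raise ValueError("regime must be 'quasi_static' or 'high_rate'")
        if not math.isfinite(self.tangent_modulus):
            raise ValueError("tangent modulus must be finite")


def tangent_modulus(curve: StressStrainCurve, at_strain: float = 0.05,
                    window: float = 0.005) -> float:
    """Central-difference slope (kPa per unit strain) at ``at_strain``.

    Uses linearly interpolated stresses at ``at_strain +/- window``; exact
    for quadratic stress-strain responses regardless of the sampling grid.
    """
    lo, hi = at_strain - window, at_strain + window
    if lo < curve.true_strain[0] or hi > curve.true_strain[-1]:
        raise ValueError(
            f"evaluation window [{lo:.4f}, {hi:.4f}] exceeds the curve's "
            f"strain range [{curve.true_strain[0]:.4f}, "
            f"{curve.true_strain[-1]:.4f}]")
    return float((curve.stress_at(hi) - curve.stress_at(lo)) / (2.0 * window))


def find_transition(curve: StressStrainCurve, regime: str,
                    criterion_strain: float = 0.05,
                    prominence: float = 0.02,
                    method: str | None = None,
                    offset: float = 0.002) -> tuple[float, float]:
    """Elastic-inelastic transition point ``(stress kPa, strain)``.

    ``regime="high_rate"`` (method ``"peak"``): the first interior local
    stress maximum whose subsequent dip exceeds ``prominence`` x the peak
    (noise guard); raises :class:`TransitionNotFoundError` when no such peak
    exists.  ``regime="quasi_static"`` (method ``"criterion"``): the stress
    at ``criterion_strain`` (the 5% true-strain criterion by default).

    ``method="offset"`` overrides either default with an offset-yield rule
    (intersection with the initial elastic slope offset by ``offset``
    strain), appropriate for ductile, monotone work-hardening curves such
    as dry brain.
    """
    if regime not in ("quasi_static", "high_rate"):
        raise ValueError("regime must be 'quasi_static' or 'high_rate'")
    if method is None:
        method = "peak" if regime == "high_rate" else "criterion"
    if method not in ("peak", "criterion", "offset"):
        raise ValueError("method must be 'peak', 'criterion' or 'offset'")
    strain, stress = curve.true_strain, curve.true_stress
    if method == "criterion":
        if not strain[0] <= criterion_strain <= strain[-1]:
            raise ValueError("criterion strain outside the curve range")
        return float(curve.stress_at(criterion_strain)), float(criterion_strain)
    if method == "offset":
        return _offset_yield(curve, offset)

    n = stress.size
    for i in range(1, n - 1):
        if stress[i] >= stress[i - 1] and stress[i] > stress[i + 1]:
            peak = stress[i]
            if peak <= 0:
                continue
            # depth of the subsequent dip before the curve re-exceeds the peak
            j = i + 1
            dip = peak
            while j < n and stress[j] < peak:
                dip = min(dip, stress[j])
                j += 1
            if (peak - dip) >= prominence * peak:
                return float(peak), float(strain[i])
    raise TransitionNotFoundError(
        "no interior stress maximum with sufficient prominence; the curve "
        "may be monotone (quasi-static morphology)")


def _offset_yield(curve: StressStrainCurve, offset: float) -> tuple[float, float]:
    """Offset-yield point: intersection of the curve with the initial
    elastic slope shifted by ``offset`` strain."""
    strain, stress = curve.true_strain, curve.true_stress
    toe = stress <= 0.4 * stress.max()
    if np.sum(toe) < 2:
        toe = np.arange(strain.size) < max(2, strain.size // 5)
    slope = float(np.linalg.lstsq(
        strain[toe, None], stress[toe], rcond=None)[0][0])
    if slope <= 0:
        raise TransitionNotFoundError("no positive initial slope for the "
                                      "offset-yield construction")
    gap = stress - slope * (strain - offset)
    below = np.nonzero(gap < 0)[0]
    below = below[strain[below] > offset]
    if below.size == 0:
        raise TransitionNotFoundError("curve never crosses the offset line")
    i = below[0]
    f = gap[i - 1] / (gap[i - 1] - gap[i]) if i > 0 else 0.0
    eps = strain[i - 1] + f * (strain[i] - strain[i - 1]) if i > 0 else strain[i]
    return float(curve.stress_at(eps)), float(eps)


def extract_metrics(curve: StressStrainCurve, regime: str | None = None,
                    tangent_at: float = 0.05,
                    criterion_strain: float = 0.05,
                    transition_method: str | None = None) -> CurveMetrics:
    """Metrics of one curve; the regime defaults to high-rate at
    >= 50 1/s."""
    if regime is None:
        regime = ("high_rate" if curve.nominal_rate >= HIGH_RATE_THRESHOLD
                  else "quasi_static")
    sigma, eps = find_transition(curve, regime, criterion_strain=criterion_strain,
                                 method=transition_method)
    return CurveMetrics(
        tangent_modulus=tangent_modulus(curve, at_strain=tangent_at),
        transition_stress=sigma, transition_strain=eps,
        regime=regime, rate=float(curve.nominal_rate))


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value.

    Degenerate inputs (fewer than two groups, any group with n < 2, or zero
    within-group variance) are rejected.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group; the "
                         "F statistic is undefined")
    f_stat, p = stats.f_oneway(*arrays)
    return float(f_stat), float(p)


def holm_sidak(pairwise_p: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm-Sidak decisions (True = reject) in input order.

    The p values are sorted ascending; the i-th smallest (1-based) is tested
    at ``1 - (1 - alpha)^(1/(k - i + 1))`` and testing stops at the first
    non-rejection, so the rejections always form a prefix of the sorted
    sequence.
    """
    p = np.asarray(pairwise_p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(k, dtype=bool)
    for rank, idx in enumerate(order):
        threshold = 1.0 - (1.0 - alpha) ** (1.0 / (k - rank))
        if p[idx] <= threshold:
            reject[idx] = True
        else:
            break
    return reject


@dataclass
class GroupComparison:
    """One-way ANOVA plus Holm-Sidak pairwise decisions across rate groups."""

    labels: tuple
    n: tuple
    means: tuple
    sems: tuple
    f_statistic: float
    p_value: float
    alpha: float
    pairwise: pd.DataFrame          # columns: a, b, p_raw, reject

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def summary(self) -> pd.DataFrame:
        """Mean +/- SE per group, mirroring the usual rate-table layout."""
        return pd.DataFrame({"group": self.labels, "n": self.n,
                             "mean": self.means, "sem": self.sems})


def compare_groups(groups: Sequence[Sequence[float]],
                   labels: Sequence | None = None,
                   alpha: float = 0.05) -> GroupComparison:
    """Full comparison: ANOVA across groups, pairwise two-sample t tests,
    Holm-Sidak correction of the pairwise p values."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = tuple(range(len(arrays)))
    f_stat, p = one_way_anova(arrays)
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    p_raw = [float(stats.ttest_ind(arrays[i], arrays[j]).pvalue)
             for i, j in pairs]
    reject = holm_sidak(p_raw, alpha=alpha)
    pairwise = pd.DataFrame({
        "a": [labels[i] for i, _ in pairs],
        "b": [labels[j] for _, j in pairs],
        "p_raw": p_raw,
        "reject": reject,
    })
    return GroupComparison(
        labels=tuple(labels), n=tuple(a.size for a in arrays),
        means=tuple(float(a.mean()) for a in arrays),
        sems=tuple(float(stats.sem(a)) for a in arrays),
        f_statistic=f_stat, p_value=p, alpha=alpha, pairwise=pairwise)


@dataclass
class RateDependence:
    """Least-squares linear trend of transition stress versus strain rate."""

    slope: float                  # kPa per (1/s)
    intercept: float              # kPa
    r_squared: float
    rates: np.ndarray
    values: np.ndarray


def rate_dependence_summary(metrics: Sequence[CurveMetrics]) -> RateDependence:
    """Linear fit of transition stress (sigma_p) against strain rate.

    Requires metrics at three or more distinct rates; group replicates at
    the same rate enter individually.
    """
    rates = np.array([m.rate for m in metrics], dtype=float)
    values = np.array([m.transition_stress for m in metrics], dtype=float)
    if np.unique(rates).size < 3:
        raise ValueError("need metrics at >= 3 distinct strain rates")
    fit = stats.linregress(rates, values)
    return RateDependence(slope=float(fit.slope),
                          intercept=float(fit.intercept),
                          r_squared=float(fit.rvalue ** 2),
                          rates=rates, values=values)


def metrics_table(metrics: Sequence[CurveMetrics]) -> pd.DataFrame:
    """Tidy metrics table (rate, regime, tangent_modulus_kPa,
    transition_stress_kPa, transition_strain)."""
    return pd.DataFrame({
        "rate_per_s": [m.rate for m in metrics],
        "regime": [m.regime for m in metrics],
        "tangent_modulus_kPa": [m.tangent_modulus for m in metrics],
        "transition_stress_kPa": [m.transition_stress for m in metrics],
        "transition_strain": [m.transition_strain for m in metrics],
    })
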