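"""Curve metrics, ANOVA and the step-down Holm-Sidak procedure."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from brainmech.constitutive import StressStrainCurve
from brainmech.mech_analysis import (TransitionNotFoundError, compare_groups,
                                     extract_metrics, find_transition,
                                     holm_sidak, one_way_anova,
                                     rate_dependence_summary, tangent_modulus)
from brainmech.synthetic import default_template, generate_curve


def make_curve(strain, stress, rate=1.0):
    return StressStrainCurve(np.asarray(strain), np.asarray(stress), rate)


class TestTangentModulus:
    def test_exact_on_linear_curve(self):
        e = np.linspace(0.0, 0.2, 100)
        assert tangent_modulus(make_curve(e, 3.0 * e)) == pytest.approx(3.0)

    def test_exact_on_quadratic_curve(self):
        # grid chosen so the window endpoints are sample points: the central
        # difference is then exact for quadratics
        e = np.linspace(0.0, 0.2, 401)
        assert tangent_modulus(make_curve(e, e ** 2)) == pytest.approx(
            0.1, rel=1e-9)

    def test_window_outside_range_rejected(self):
        e = np.linspace(0.02, 0.2, 50)
        with pytest.raises(ValueError, match="window"):
            tangent_modulus(make_curve(e, e), at_strain=0.02)

    def test_noisy_linear_estimate_converges_with_window(self):
        rng = np.random.default_rng(17)
        e = np.linspace(0.0, 0.2, 2000)
        s = 5.0 * e + 0.002 * rng.standard_normal(e.size)
        errs = [abs(tangent_modulus(make_curve(e, s), window=w) - 5.0)
                for w in (0.002, 0.01, 0.04)]
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.25  # within 5% of the true slope


class TestFindTransition:
    def test_constructed_peak_located_exactly(self):
        t = default_template("wet_hr", 250.0)
        curve = generate_curve(t, seed=0)
        stress, strain = find_transition(curve, "high_rate")
        assert strain == pytest.approx(t.transition_strain)
        assert stress == pytest.approx(t.transition_stress)

    def test_monotone_curve_uses_five_percent_criterion(self):
        e = np.linspace(0.0, 0.2, 100)
        stress, strain = find_transition(make_curve(e, 2.0 * e),
                                         "quasi_static")
        assert strain == 0.05
        assert stress == pytest.approx(0.1)

    def test_monotone_high_rate_curve_raises_not_found(self):
        e = np.linspace(0.0, 0.2, 100)
        with pytest.raises(TransitionNotFoundError):
            find_transition(make_curve(e, 2.0 * e), "high_rate")

    def test_noise_spike_peaks_are_ignored(self):
        e = np.linspace(0.0, 0.2, 200)
        s = 10.0 * e
        s[60] *= 1.005  # 0.5% blip, below the 2% prominence guard
        with pytest.raises(TransitionNotFoundError):
            find_transition(make_curve(e, s), "high_rate")

    def test_offset_yield_on_bilinear_curve(self):
        t = default_template("dry", 250.0)
        curve = generate_curve(t, seed=0)
        stress, strain = find_transition(curve, "quasi_static",
                                         method="offset")
        assert strain == pytest.approx(t.transition_strain, rel=0.10)
        assert stress == pytest.approx(t.transition_stress, rel=0.10)

    def test_quasi_static_template_anchor_matches_reported_statistics(self):
        # the default quasi-static wet template anchors the transition at
        # 7.5% strain; the criterion rule recovers the anchored stress when
        # evaluated there
        t = default_template("wet_qs", 0.00625)
        assert t.transition_strain == 0.075
        curve = generate_curve(t, seed=0)
        stress, strain = find_transition(curve, "quasi_static",
                                         criterion_strain=0.075)
        assert strain == 0.075
        assert stress == pytest.approx(0.1046, rel=0.01)


class TestOneWayAnova:
    def test_no_between_group_variance(self):
        f, p = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_example_against_brute_force(self):
        groups = [[6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
                  [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
                  [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]]
        # brute-force sums of squares
        flat = np.concatenate(groups)
        grand = flat.mean()
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum()
                        for g in groups)
        df_b, df_w = len(groups) - 1, flat.size - len(groups)
        f_expected = (ss_between / df_b) / (ss_within / df_w)
        f, p = one_way_anova(groups)
        assert f == pytest.approx(f_expected, rel=1e-12)
        assert 0.0 < p < 1.0

    def test_shift_invariance(self):
        groups = [[1.0, 2.0, 4.0], [2.0, 5.0, 6.0], [1.5, 2.5, 3.0]]
        f1, p1 = one_way_anova(groups)
        f2, p2 = one_way_anova([[x + 100.0 for x in g] for g in groups])
        assert f1 == pytest.approx(f2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError, match="variance"):
            one_way_anova([[2.0, 2.0], [2.0, 2.0]])


def brute_force_holm_sidak(pvals, alpha):
    """Literal step-down enumeration used as the independent oracle."""
    k = len(pvals)
    order = np.argsort(pvals, kind="stable")
    reject = [False] * k
    for step, idx in enumerate(order):
        threshold = 1.0 - (1.0 - alpha) ** (1.0 / (k - step))
        if pvals[idx] <= threshold:
            reject[idx] = True
        else:
            break
    return np.asarray(reject)


class TestHolmSidak:
    def test_no_rejections_at_unit_p(self):
        assert not holm_sidak([1.0, 1.0, 1.0]).any()

    def test_single_comparison_reduces_to_alpha(self):
        assert holm_sidak([0.049]).tolist() == [True]
        assert holm_sidak([0.051]).tolist() == [False]

    def test_three_comparison_example_matches_enumeration(self):
        p = [0.001, 0.02, 0.04]
        assert np.array_equal(holm_sidak(p),
                              brute_force_holm_sidak(p, 0.05))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6),
           st.sampled_from([0.01, 0.05, 0.10]))
    def test_matches_brute_force_and_prefix_property(self, pvals, alpha):
        decisions = holm_sidak(pvals, alpha=alpha)
        assert np.array_equal(decisions,
                              brute_force_holm_sidak(pvals, alpha))
        # rejections form a prefix of the sorted p values
        ranked = decisions[np.argsort(pvals, kind="stable")]
        assert all(ranked[i] or not ranked[i + 1]
                   for i in range(len(ranked) - 1))
        # fewer rejections at a stricter alpha
        stricter = holm_sidak(pvals, alpha=alpha / 2)
        assert stricter.sum() <= decisions.sum()

    @given(st.lists(st.floats(0.0001, 0.9999), min_size=2, max_size=6))
    def test_matches_statsmodels_reference(self, pvals):
        mine = holm_sidak(pvals, alpha=0.05)
        reference = multipletests(pvals, alpha=0.05, method="holm-sidak")[0]
        assert np.array_equal(mine, reference)


class TestGroupComparison:
    def test_summary_layout_and_decisions(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0.0, 1.0, 8), rng.normal(0.2, 1.0, 8),
                  rng.normal(5.0, 1.0, 8)]
        cmp_res = compare_groups(groups, labels=["a", "b", "c"])
        assert cmp_res.significant
        assert list(cmp_res.pairwise.columns) == ["a", "b", "p_raw",
                                                  "reject"]
        decisions = dict(zip(zip(cmp_res.pairwise["a"],
                                 cmp_res.pairwise["b"]),
                             cmp_res.pairwise["reject"]))
        assert decisions[("a", "c")] and decisions[("b", "c")]
        assert not decisions[("a", "b")]
        summary = cmp_res.summary()
        assert list(summary.columns) == ["group", "n", "mean", "sem"]


class TestRateDependence:
    def make_metrics(self, rates, values):
        curves = []
        for r, v in zip(rates, values):
            t = default_template("wet_hr", r)
            t = t.__class__(**{**t.__dict__, "transition_stress": v})
            curves.append(generate_curve(t, seed=1))
        return [extract_metrics(c, regime="high_rate") for c in curves]

    def test_exactly_linear_values_give_unit_r_squared(self):
        rates = [50.0, 250.0, 450.0, 750.0]
        mets = self.make_metrics(rates, [10 + 0.05 * r for r in rates])
        fit = rate_dependence_summary(mets)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(0.05, rel=1e-6)

    def test_constant_values_give_zero_slope(self):
        rates = [50.0, 250.0, 750.0]
        mets = self.make_metrics(rates, [20.0, 20.0, 20.0])
        assert rate_dependence_summary(mets).slope == pytest.approx(0.0,
                                                                    abs=1e-9)

    def test_synthetic_defaults_show_positive_rate_hardening(self):
        rates = [50.0, 250.0, 450.0, 550.0, 750.0]
        mets = [extract_metrics(generate_curve(default_template("wet_hr", r),
                                               seed=4), regime="high_rate")
                for r in rates]
        assert rate_dependence_summary(mets).slope > 0

    def test_too_few_rates_rejected(self):
        mets = self.make_metrics([50.0, 250.0], [10.0, 20.0])
        with pytest.raises(ValueError, match="3 distinct"):
            rate_dependence_summary(mets)
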