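"""Tracer-incubation rate estimators and the stoichiometric budget logic."""

import numpy as np
import pytest

from odzrates import (
    RateEstimate,
    TracerTimeCourse,
    anammox_coupled_oxidation,
    atom_fraction,
    disproportionation_n2_share,
    fit_linear_rate,
    n2_pairing_rates,
    nitrite_oxidation_rate,
    o2_budget,
    pairing_slopes,
)

from _oracles import mc_pairing_fractions, ols_slope_closed_form


def course(times, values, analyte="no3_15_ex_nM", f=0.5):
    return TracerTimeCourse(times=np.asarray(times), values=np.asarray(values),
                            analyte=analyte, f_label=None if analyte == "o2_nM" else f)


class TestFitLinearRate:
    def test_exact_line(self):
        est = fit_linear_rate(course([0, 0.5, 1], [0, 5, 10]))
        assert est.rate == pytest.approx(10.0)
        assert est.se == pytest.approx(0.0, abs=1e-10)

    def test_matches_closed_form_normal_equations(self):
        t = [0, 0.5, 0.5, 1, 1]
        y = [10, 12, 13, 14, 15]
        est = fit_linear_rate(course(t, y))
        slope, se = ols_slope_closed_form(t, y)
        assert est.rate == pytest.approx(slope)
        assert est.se == pytest.approx(se)
        assert est.n == 5

    def test_reversed_time_negates_slope(self, rng):
        t = np.array([0, 0.5, 0.5, 1, 1])
        y = rng.normal(5 * t, 1.0)
        fwd = fit_linear_rate(course(t, y))
        rev = fit_linear_rate(course(t.max() - t, y))
        assert rev.rate == pytest.approx(-fwd.rate)
        assert rev.se == pytest.approx(fwd.se)

    def test_scale_equivariance(self, rng):
        t = np.array([0, 0.5, 0.5, 1, 1])
        y = rng.normal(8 * t + 2, 0.5)
        base = fit_linear_rate(course(t, y))
        doubled = fit_linear_rate(course(t, 2 * y))
        assert doubled.rate == pytest.approx(2 * base.rate)
        assert doubled.se == pytest.approx(2 * base.se)

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError, match="3 distinct time"):
            course([0, 0, 1, 1], [0, 1, 2, 3])


class TestNitriteOxidationRate:
    def test_fully_labelled_pool(self):
        est = nitrite_oxidation_rate(course([0, 0.5, 1], [0, 2.5, 5], f=1.0))
        assert est.rate == pytest.approx(5.0)

    def test_dilution_correction(self):
        est = nitrite_oxidation_rate(course([0, 0.5, 1], [0, 2.5, 5], f=0.5))
        assert est.rate == pytest.approx(10.0)
        assert est.n == 3

    def test_zero_atom_fraction_rejected(self):
        with pytest.raises(ValueError, match="f_label"):
            course([0, 0.5, 1], [0, 2.5, 5], f=0.0)

    def test_atom_fraction_from_addition(self):
        assert atom_fraction(7.24, 2.0) == pytest.approx(7.24 / 9.24)
        with pytest.raises(ValueError):
            atom_fraction(0.0, 2.0)


class TestIsotopePairing:
    def test_fully_labelled_denitrification_is_all_mass_30(self):
        tc30 = course([0, 0.5, 1], [0, 2, 4], analyte="n2_30_ex_nM", f=1.0)
        tc29 = course([0, 0.5, 1], [0, 0, 0], analyte="n2_29_ex_nM", f=1.0)
        denit, amx = n2_pairing_rates(tc29, tc30)
        assert denit.rate == pytest.approx(8.0)   # N atom units
        assert amx.rate == pytest.approx(0.0, abs=1e-12)

    def test_fully_labelled_anammox_is_all_mass_29(self):
        tc29 = course([0, 0.5, 1], [0, 1, 2], analyte="n2_29_ex_nM", f=1.0)
        tc30 = course([0, 0.5, 1], [0, 0, 0], analyte="n2_30_ex_nM", f=1.0)
        denit, amx = n2_pairing_rates(tc29, tc30)
        assert denit.rate == pytest.approx(0.0, abs=1e-12)
        assert amx.rate == pytest.approx(4.0)

    def test_continuity_toward_fully_labelled_limit(self):
        slopes = {}
        for f in (1.0, 0.999):
            p29, p30 = pairing_slopes(10.0, 4.0, f)
            tc29 = course([0, 0.5, 1], np.array([0, 0.5, 1]) * p29, "n2_29_ex_nM", f)
            tc30 = course([0, 0.5, 1], np.array([0, 0.5, 1]) * p30, "n2_30_ex_nM", f)
            denit, amx = n2_pairing_rates(tc29, tc30)
            slopes[f] = (denit.rate, amx.rate)
        np.testing.assert_allclose(slopes[0.999], slopes[1.0], rtol=1e-2)
        np.testing.assert_allclose(slopes[1.0], (10.0, 4.0), rtol=1e-12)

    @pytest.mark.parametrize("f", [0.3, 0.5, 0.9])
    def test_analytic_slopes_match_monte_carlo_pairing(self, f, rng):
        denit_n, amx_n = 10.0, 4.0
        p29, p30 = pairing_slopes(denit_n, amx_n, f)
        (q29_d, q30_d), (q29_a, _), se = mc_pairing_fractions(f, 10**6, rng)
        mc29 = (denit_n / 2) * q29_d + (amx_n / 2) * q29_a
        mc30 = (denit_n / 2) * q30_d
        # binomial SE propagated through the same linear combinations
        assert abs(mc29 - p29) <= 3 * se * (denit_n / 2 + amx_n / 2)
        assert abs(mc30 - p30) <= 3 * se * (denit_n / 2)

    def test_pairing_roundtrip_recovers_rates(self):
        """generate slopes at f = 0.3, invert with the pairing formulas."""
        f = 0.3
        p29, p30 = pairing_slopes(12.0, 5.0, f)
        t = np.array([0, 0.5, 1.0])
        tc29 = course(t, p29 * t, "n2_29_ex_nM", f)
        tc30 = course(t, p30 * t, "n2_30_ex_nM", f)
        denit, amx = n2_pairing_rates(tc29, tc30)
        assert denit.rate == pytest.approx(12.0, rel=1e-12)
        assert amx.rate == pytest.approx(5.0, rel=1e-12)

    def test_negative_anammox_reported_not_truncated(self):
        f = 0.5
        t = np.array([0, 0.5, 1.0])
        tc29 = course(t, 0.1 * t, "n2_29_ex_nM", f)
        tc30 = course(t, 2.0 * t, "n2_30_ex_nM", f)
        _, amx = n2_pairing_rates(tc29, tc30)
        assert amx.rate < 0
        assert not amx.significant


class TestSignificanceRule:
    def test_error_bar_excluding_zero(self):
        assert RateEstimate(rate=10.0, se=2.0, n=5).significant
        assert not RateEstimate(rate=3.0, se=2.0, n=5).significant
        assert not RateEstimate(rate=-1.0, se=2.0, n=5).significant


class TestBudgets:
    def test_o2_demand_is_half_the_oxidation_rate(self):
        ob = o2_budget(RateEstimate(30.0, 1.0, 5), RateEstimate(-20.0, 1.0, 32))
        assert ob.expected_o2_demand == pytest.approx(15.0)
        assert ob.classification == "aerobic-consistent"

    def test_no_o2_consumption_is_insufficient(self):
        ob = o2_budget(RateEstimate(30.0, 1.0, 5), RateEstimate(0.0, 1.0, 32))
        assert ob.classification == "O2-insufficient"

    def test_zero_oxidation_is_consistent(self):
        ob = o2_budget(RateEstimate(0.0, 0.0, 5), RateEstimate(0.0, 1.0, 32))
        assert ob.expected_o2_demand == 0.0
        assert ob.classification == "aerobic-consistent"

    def test_anammox_nitrate_side_branch(self):
        ax = anammox_coupled_oxidation(RateEstimate(10.0, 1.0, 5), no2_ox_rate=30.0, c=0.16)
        assert ax.no3_production == pytest.approx(0.8)
        assert ax.fraction_of_oxidation == pytest.approx(0.8 / 30.0)
        zero = anammox_coupled_oxidation(RateEstimate(0.0, 0.0, 5), no2_ox_rate=30.0)
        assert zero.no3_production == 0.0

    def test_anammox_fraction_undefined_without_oxidation(self):
        ax = anammox_coupled_oxidation(RateEstimate(10.0, 1.0, 5), no2_ox_rate=0.0)
        assert not ax.defined
        assert np.isnan(ax.fraction_of_oxidation)

    def test_anammox_fraction_recovers_seven_percent(self, rng):
        """Pairs drawn so the true nitrate-branch share is 7% of oxidation."""
        c = 0.16
        true_frac = 0.07
        for _ in range(50):
            amx = rng.uniform(5.0, 20.0)
            ox = c * amx / 2.0 / true_frac
            ax = anammox_coupled_oxidation(RateEstimate(amx, 0.5, 5), no2_ox_rate=ox, c=c)
            assert ax.fraction_of_oxidation == pytest.approx(true_frac, rel=1e-12)

    @pytest.mark.parametrize(
        "ox, n2, expected",
        [(30.0, 20.0, 1.0), (30.0, 100.0, 0.2), (0.0, 50.0, 0.0)],
    )
    def test_disproportionation_share_closed_form(self, ox, n2, expected):
        share = disproportionation_n2_share(RateEstimate(ox, 1.0, 5),
                                            RateEstimate(n2, 1.0, 5))
        assert share.share == pytest.approx(expected)
        assert share.defined

    def test_disproportionation_share_flags(self):
        over = disproportionation_n2_share(RateEstimate(60.0, 1.0, 5),
                                           RateEstimate(20.0, 1.0, 5))
        assert over.share == pytest.approx(2.0)
        assert over.exceeds_unity
        undef = disproportionation_n2_share(RateEstimate(10.0, 1.0, 5),
                                            RateEstimate(0.0, 1.0, 5))
        assert not undef.defined
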