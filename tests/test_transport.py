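"""The 1-D steady-state transport operator, both directions."""

import numpy as np
import pytest

from odzrates import (
    DepthProfile,
    FractionationSet,
    TransportParams,
    build_stoichiometry_matrix,
    IsotopeState,
    net_rate_from_profile,
    solve_steady_state,
    transport_rate_uM,
)


def flat_profile(n=11, value=2.0):
    z = np.linspace(0.0, 100.0, n)
    c = np.full(n, value)
    return DepthProfile(z=z, conc_14nh4=c, conc_14no2=c, conc_14no3=c,
                        conc_15no2=0.004 * c, conc_15no3=0.004 * c)


class TestNetRateFromProfile:
    def test_constant_profile_has_zero_rates(self):
        out = net_rate_from_profile(flat_profile(), TransportParams(kz=10.0, w=0.3))
        for col in ("r_14nh4", "r_14no2", "r_14no3", "r_15no2", "r_15no3"):
            np.testing.assert_allclose(out[col], 0.0, atol=1e-12)

    def test_linear_profile_without_advection(self):
        z = np.linspace(0.0, 100.0, 11)
        c = 1.0 + 0.05 * z
        p = DepthProfile(z=z, conc_14nh4=c, conc_14no2=c, conc_14no3=c,
                         conc_15no2=0.004 * c, conc_15no3=0.004 * c)
        out = net_rate_from_profile(p, TransportParams(kz=10.0, w=0.0))
        np.testing.assert_allclose(out["r_14no2"], 0.0, atol=1e-9)

    def test_quadratic_profile_closed_form(self):
        # C = z^2 µM, kz = 100 m^2/d, w = 0: R = -kz d2C/dz2 = -200 µM/d
        z = np.linspace(0.0, 10.0, 11)
        c = z**2
        raw = transport_rate_uM(z, c, TransportParams(kz=100.0, w=0.0))
        np.testing.assert_allclose(raw, -200.0, rtol=1e-12)
        p = DepthProfile(z=z, conc_14nh4=c, conc_14no2=c, conc_14no3=c,
                         conc_15no2=0.004 * c, conc_15no3=0.004 * c)
        out = net_rate_from_profile(p, TransportParams(kz=100.0, w=0.0))
        np.testing.assert_allclose(out["r_14no3"], -2.0e5, rtol=1e-12)  # nM d-1

    def test_nonuniform_grid_rejected_with_spacing_message(self):
        z = np.array([0.0, 10.0, 25.0, 30.0, 40.0, 50.0])
        c = np.ones_like(z)
        p = DepthProfile(z=z, conc_14nh4=c, conc_14no2=c, conc_14no3=c,
                         conc_15no2=c * 0.004, conc_15no3=c * 0.004)
        with pytest.raises(ValueError, match="non-uniform"):
            net_rate_from_profile(p, TransportParams(kz=10.0))
        out = net_rate_from_profile(p, TransportParams(kz=10.0), regrid=True)
        np.testing.assert_allclose(out["r_14nh4"], 0.0, atol=1e-8)


class TestDepthProfileValidation:
    def test_duplicate_depth_rejected(self):
        z = np.array([0.0, 10.0, 10.0, 30.0, 40.0])
        c = np.ones_like(z)
        with pytest.raises(ValueError, match="duplicate depth 10"):
            DepthProfile(z=z, conc_14nh4=c, conc_14no2=c, conc_14no3=c,
                         conc_15no2=c, conc_15no3=c)

    def test_short_grid_rejected(self):
        z = np.arange(4.0)
        c = np.ones(4)
        with pytest.raises(ValueError, match=">= 5 points"):
            DepthProfile(z=z, conc_14nh4=c, conc_14no2=c, conc_14no3=c,
                         conc_15no2=c, conc_15no3=c)

    def test_totals_delta_roundtrip(self):
        z = np.linspace(100.0, 200.0, 6)
        p = DepthProfile.from_totals_and_delta(
            z, nh4_uM=np.full(6, 0.2), no2_uM=np.full(6, 1.5), no3_uM=np.full(6, 25.0),
            d15n_no2_permil=np.full(6, -12.0), d15n_no3_permil=np.full(6, 16.0),
        )
        df = p.to_dataframe()
        np.testing.assert_allclose(df["no2_uM"], 1.5, rtol=1e-12)
        np.testing.assert_allclose(df["d15n_no2_permil"], -12.0, atol=1e-9)
        np.testing.assert_allclose(df["d15n_no3_permil"], 16.0, atol=1e-9)


BOUNDARY = {
    "nh4": (1.0, 1.0),
    "no2": (60.0, 60.0),
    "no3": (60.0, 60.0),
    "d15n_no2": (0.0, 0.0),
    "d15n_no3": (0.0, 0.0),
}


class TestSolveSteadyState:
    def test_no_rates_equal_boundaries_gives_constant(self, stoich, alphas):
        z = np.linspace(0.0, 100.0, 21)
        prof = solve_steady_state(np.zeros((21, 4)), BOUNDARY, z,
                                  TransportParams(kz=20.0, w=0.0), stoich, alphas)
        np.testing.assert_allclose(prof.conc_14nh4, 1.0, rtol=1e-10)
        tot_no2 = prof.conc_14no2 + prof.conc_15no2
        np.testing.assert_allclose(tot_no2, 60.0, rtol=1e-10)

    @staticmethod
    def _manufactured_error(n):
        """Solve with sources derived from a prescribed smooth ammonium
        profile and return the max deviation from it."""
        kz, w = 50.0, 1.5
        L = 100.0
        z = np.linspace(0.0, L, n)
        k = np.pi / L
        c_star = 5.0 + 2.0 * np.sin(k * z)                  # µM
        r_star = w * 2.0 * k * np.cos(k * z) - kz * (-2.0 * k**2 * np.sin(k * z))
        # realise R* through the ammonium source terms: remineralisation
        # (f_nir) where production is needed, anammox where consumption is
        F = np.zeros((n, 4))
        F[:, 0] = np.clip(r_star, 0.0, None) / 0.11 * 1e3   # f_nir, nM/d
        F[:, 2] = np.clip(-r_star, 0.0, None) * 1e3         # f_amx
        bd = dict(BOUNDARY)
        bd["nh4"] = (c_star[0], c_star[-1])
        prof = solve_steady_state(F, bd, z, TransportParams(kz=kz, w=w))
        return float(np.max(np.abs(prof.conc_14nh4 - c_star)))

    def test_manufactured_solution_second_order_convergence(self):
        errs = [self._manufactured_error(n) for n in (26, 51, 101)]
        ratios = [errs[i] / errs[i + 1] for i in range(2)]
        for r in ratios:
            assert 3.3 < r < 4.8, f"expected ~4x error reduction per halving, got {ratios}"

    def test_discrete_roundtrip_matches_network_map(self, clean_scenario, clean_profile,
                                                    stoich, alphas):
        """Differencing the forward solution returns exactly A(z) F(z)."""
        profile, truth = clean_profile
        t = clean_scenario.transport
        R = net_rate_from_profile(profile, t)
        r2, r3 = profile.isotope_ratios()
        F = truth[["f_nir", "f_nar", "f_amx", "f_dis"]].to_numpy()
        for i in range(1, profile.z.size - 1):
            A = build_stoichiometry_matrix(stoich, alphas,
                                           IsotopeState(r_no2=r2[i], r_no3=r3[i]))
            expected = A @ F[i]
            got = R.iloc[i - 1][["r_14nh4", "r_14no2", "r_14no3",
                                 "r_15no2", "r_15no3"]].to_numpy(float)
            np.testing.assert_allclose(got, expected, rtol=1e-8,
                                       atol=1e-8 * max(1.0, np.abs(expected).max()))

    def test_uniform_isotope_ratio_without_fractionation(self, clean_scenario, stoich):
        """All alpha = 1 and common boundary delta: the 15N pools are an
        exact scalar multiple of the 14N pools at every depth."""
        sc = clean_scenario
        bd = dict(sc.boundary)
        bd["d15n_no2"] = (5.0, 5.0)
        bd["d15n_no3"] = (5.0, 5.0)
        F = sc.true_rates()[["f_nir", "f_nar", "f_amx", "f_dis"]].to_numpy()
        prof = solve_steady_state(F, bd, sc.z, sc.transport, stoich,
                                  FractionationSet.no_fractionation())
        r = 0.0036765 * 1.005
        np.testing.assert_allclose(prof.conc_15no2, r * prof.conc_14no2, rtol=1e-10)
        np.testing.assert_allclose(prof.conc_15no3, r * prof.conc_14no3, rtol=1e-10)

    def test_linearity_of_14n_solve(self, stoich, alphas, rng):
        z = np.linspace(0.0, 200.0, 21)
        F = rng.uniform(0.0, 5.0, size=(21, 4))
        t = TransportParams(kz=30.0, w=0.5)
        p1 = solve_steady_state(F, BOUNDARY, z, t, stoich, alphas)
        bd2 = {k: (2 * a, 2 * b) if not k.startswith("d15n") else (a, b)
               for k, (a, b) in BOUNDARY.items()}
        p2 = solve_steady_state(2.0 * F, bd2, z, t, stoich, alphas)
        np.testing.assert_allclose(p2.conc_14nh4, 2.0 * p1.conc_14nh4, rtol=1e-9)
        np.testing.assert_allclose(p2.conc_14no3, 2.0 * p1.conc_14no3, rtol=1e-9)

    def test_negative_solution_flagged_not_clipped(self, stoich, alphas):
        z = np.linspace(0.0, 100.0, 21)
        F = np.zeros((21, 4))
        F[:, 2] = 50.0  # anammox draw-down far beyond the ammonium supply
        bd = dict(BOUNDARY)
        bd["nh4"] = (0.05, 0.05)
        with pytest.warns(RuntimeWarning, match="undershoots zero"):
            prof = solve_steady_state(F, bd, z, TransportParams(kz=20.0), stoich, alphas)
        assert prof.negative_values
        assert prof.conc_14nh4.min() < 0
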