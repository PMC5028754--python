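"""Binding isotherms: solvers, forward model, fits, profiles, thermodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import picsfit as pf
from picsfit.itc import R_KCAL, OneSiteParams, TwoSiteParams
from conftest import bisect_root


def one_site_balance(Mt, Lt, params):
    def f(ml):
        free_m_sites = params.N * Mt - ml
        free_l = Lt - ml
        return free_m_sites * free_l - params.Kd * ml
    return f


class TestBoundFractionOneSite:
    def test_stoichiometric_limits(self):
        tight = OneSiteParams(N=1.0, Kd=1e-12, dH=-5.0)
        assert pf.bound_fraction_one_site(10.0, 4.0, tight) == pytest.approx(4.0)
        assert pf.bound_fraction_one_site(10.0, 25.0, tight) == pytest.approx(10.0)
        loose = OneSiteParams(N=1.0, Kd=1e12, dH=-5.0)
        assert pf.bound_fraction_one_site(10.0, 4.0, loose) == pytest.approx(0.0, abs=1e-6)

    def test_printed_concentration_point_vs_bisection(self):
        params = OneSiteParams(N=1.0, Kd=43.0, dH=-5.0)
        got = pf.bound_fraction_one_site(64.8, 64.8, params)
        oracle = bisect_root(one_site_balance(64.8, 64.8, params), 0.0, 64.8)
        assert got == pytest.approx(oracle, abs=1e-8)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            pf.bound_fraction_one_site(-1.0, 1.0, OneSiteParams(1, 1, -5))


class TestFreeLigandTwoSites:
    def test_no_macromolecule(self):
        p = TwoSiteParams(Kd1=10, Kd2=100, dH1=-5, dH2=-5)
        assert pf.free_ligand_two_sites(0.0, 50.0, p) == pytest.approx(50.0)

    def test_equal_sites_match_one_site_n2(self):
        p2 = TwoSiteParams(Kd1=50.0, Kd2=50.0, dH1=-5, dH2=-5)
        p1 = OneSiteParams(N=2.0, Kd=50.0, dH=-5)
        for Mt, Lt in [(97.0, 150.0), (10.0, 5.0), (3.0, 40.0)]:
            free = pf.free_ligand_two_sites(Mt, Lt, p2)
            bound1 = pf.bound_fraction_one_site(Mt, Lt, p1)
            assert free == pytest.approx(Lt - bound1, abs=1e-8)

    def test_printed_concentration_point_vs_bisection(self):
        p = TwoSiteParams(Kd1=175.0, Kd2=575.0, dH1=-5, dH2=-5)
        got = pf.free_ligand_two_sites(97.0, 150.0, p)
        oracle = bisect_root(
            lambda L: L + 97.0 * L / (175.0 + L) + 97.0 * L / (575.0 + L) - 150.0,
            0.0, 150.0,
        )
        assert got == pytest.approx(oracle, abs=1e-8)


@given(
    Mt=st.floats(0.01, 5000.0),
    Lt=st.floats(0.01, 5000.0),
    N=st.floats(0.2, 4.0),
    kd1=st.floats(1e-3, 1e5),
    kd2=st.floats(1e-3, 1e5),
)
@settings(max_examples=1000, derandomize=True, deadline=None)
def test_solvers_agree_with_bisection_oracle(Mt, Lt, N, kd1, kd2):
    """Both mass-balance solvers track a hand-rolled bisection to 1e-8 and
    conserve ligand to 1e-10 relative."""
    one = OneSiteParams(N=N, Kd=kd1, dH=-5.0)
    bound = pf.bound_fraction_one_site(Mt, Lt, one)
    oracle = bisect_root(one_site_balance(Mt, Lt, one), 0.0, min(Lt, N * Mt))
    assert bound == pytest.approx(oracle, abs=1e-8 * max(1.0, Lt))
    # mass conservation: free + bound = total
    free = Lt - bound
    assert abs(free + bound - Lt) <= 1e-10 * max(1.0, Lt)

    two = TwoSiteParams(Kd1=kd1, Kd2=kd2, dH1=-5.0, dH2=-5.0)
    L = pf.free_ligand_two_sites(Mt, Lt, two)
    oracle2 = bisect_root(
        lambda x: x + Mt * x / (kd1 + x) + Mt * x / (kd2 + x) - Lt, 0.0, Lt
    )
    assert L == pytest.approx(oracle2, abs=1e-8 * max(1.0, Lt))
    total = L + Mt * L / (kd1 + L) + Mt * L / (kd2 + L)
    assert abs(total - Lt) <= 1e-10 * max(1.0, Lt)


class TestModelHeats:
    def test_zero_enthalpy_gives_offset(self, rvp_uba_protocol):
        p = OneSiteParams(N=1.0, Kd=43.0, dH=0.0, offset=0.7)
        np.testing.assert_allclose(pf.model_heats(rvp_uba_protocol, p), 0.7)

    def test_linearity_in_enthalpy(self, full_length_protocol):
        base = TwoSiteParams(Kd1=175, Kd2=575, dH1=-5, dH2=-3, offset=0.2)
        double = TwoSiteParams(Kd1=175, Kd2=575, dH1=-10, dH2=-6, offset=0.2)
        h1 = pf.model_heats(full_length_protocol, base)
        h2 = pf.model_heats(full_length_protocol, double)
        np.testing.assert_allclose(h2 - 0.2, 2.0 * (h1 - 0.2), rtol=1e-12)

    def test_tight_binding_step_at_molar_ratio_n(self, rvp_uba_protocol):
        p = OneSiteParams(N=1.5, Kd=1e-9, dH=-5.0)
        tit = pf.simulate_isotherm(rvp_uba_protocol, p)
        ratio = tit.molar_ratio
        norm = tit.normalized
        assert np.allclose(norm[ratio < 1.35], -5.0, atol=1e-2)
        assert np.allclose(norm[ratio > 1.65], 0.0, atol=1e-2)

    def test_two_site_collapse_to_one_site(self, full_length_protocol):
        h2 = pf.model_heats(full_length_protocol,
                            TwoSiteParams(Kd1=320, Kd2=320, dH1=-5, dH2=-5))
        h1 = pf.model_heats(full_length_protocol,
                            OneSiteParams(N=2.0, Kd=320, dH=-5))
        np.testing.assert_allclose(h2, h1, atol=1e-10)


class TestFitOneSite:
    @pytest.mark.parametrize("c", [1.0, 10.0, 100.0, 1000.0])
    def test_round_trip_recovery_across_c_range(self, c):
        """simulate (noiseless) -> fit recovers N, Kd, dH within 1%."""
        m0 = 100.0
        truth = OneSiteParams(N=1.0, Kd=m0 / c, dH=-5.0)
        protocol = pf.InjectionProtocol.uniform(30, 9.0, 1.43, m0, 12.0 * m0)
        tit = pf.simulate_isotherm(protocol, truth)
        fit = pf.fit_one_site(tit, init=truth.perturbed(1.5))
        assert fit.success
        assert fit.params.N == pytest.approx(truth.N, rel=0.01)
        assert fit.params.Kd == pytest.approx(truth.Kd, rel=0.01)
        assert fit.params.dH == pytest.approx(truth.dH, rel=0.01)

    def test_pure_offset_data_flagged_unidentifiable(self, rvp_uba_protocol):
        flat = pf.simulate_isotherm(rvp_uba_protocol,
                                    OneSiteParams(N=1.0, Kd=43.0, dH=0.0, offset=0.5))
        fit = pf.fit_one_site(flat, init=OneSiteParams(1.0, 50.0, -1.0, 0.5),
                              fit_offset=True)
        assert abs(fit.params.dH) < 1e-3
        assert not fit.kd_identifiable

    def test_fix_n_is_held(self, rvp_uba_protocol):
        truth = OneSiteParams(N=1.0, Kd=43.0, dH=-5.0)
        tit = pf.simulate_isotherm(rvp_uba_protocol, truth)
        fit = pf.fit_one_site(tit, init=truth.perturbed(1.5), fix_N=1.0)
        assert fit.params.N == 1.0
        assert fit.params.Kd == pytest.approx(43.0, rel=0.01)

    def test_too_few_injections_rejected(self):
        protocol = pf.InjectionProtocol.uniform(3, 9.0, 1.43, 64.8, 796.0)
        tit = pf.simulate_isotherm(protocol, OneSiteParams(1.0, 43.0, -5.0))
        with pytest.raises(ValueError):
            pf.fit_one_site(tit)

    def test_chi2_never_above_initialization(self, rvp_uba_protocol):
        truth = OneSiteParams(N=1.0, Kd=43.0, dH=-5.0)
        tit = pf.simulate_isotherm(rvp_uba_protocol, truth, noise_sd=0.05, seed=9)
        init = truth.perturbed(1.8)
        chi2_init = float(np.sum(
            (tit.normalized - pf.model_heats(rvp_uba_protocol, init)) ** 2))
        fit = pf.fit_one_site(tit, init=init)
        assert fit.chi2 <= chi2_init + 1e-12


class TestFitTwoSites:
    def test_round_trip_recovery_with_ordering(self, full_length_protocol):
        truth = TwoSiteParams(Kd1=575.0, Kd2=175.0, dH1=-3.0, dH2=-6.0)
        tit = pf.simulate_isotherm(full_length_protocol, truth)
        fit = pf.fit_two_sites(tit, init=truth.perturbed(1.5))
        assert fit.success
        p = fit.params
        assert p.Kd1 <= p.Kd2  # exchange symmetry resolved
        assert p.Kd1 == pytest.approx(175.0, rel=0.01)
        assert p.Kd2 == pytest.approx(575.0, rel=0.01)
        assert p.dH1 == pytest.approx(-6.0, rel=0.01)
        assert p.dH2 == pytest.approx(-3.0, rel=0.01)

    def test_one_site_n2_data_is_degenerate(self, full_length_protocol):
        tit = pf.simulate_isotherm(full_length_protocol,
                                   OneSiteParams(N=2.0, Kd=320.0, dH=-5.0))
        fit = pf.fit_two_sites(
            tit, init=TwoSiteParams(Kd1=200.0, Kd2=500.0, dH1=-4.0, dH2=-6.0))
        assert fit.params.Kd1 == pytest.approx(fit.params.Kd2, rel=0.1)
        assert fit.degenerate

    def test_too_few_injections_rejected(self):
        protocol = pf.InjectionProtocol.uniform(5, 9.0, 1.43, 97.0, 1420.0)
        tit = pf.simulate_isotherm(protocol, TwoSiteParams(175, 575, -5, -5))
        with pytest.raises(ValueError):
            pf.fit_two_sites(tit)


class TestChi2Profile:
    def make_titration(self, protocol):
        return pf.simulate_isotherm(protocol,
                                    TwoSiteParams(Kd1=175.0, Kd2=575.0, dH1=-5, dH2=-5))

    def test_minimum_at_generating_node(self, full_length_protocol):
        tit = self.make_titration(full_length_protocol)
        grid1 = np.array([100.0, 175.0, 300.0])
        grid2 = np.array([400.0, 575.0, 800.0])
        prof = pf.chi2_profile_two_sites(tit, grid1, grid2, threshold=1e-12)
        i, j = np.unravel_index(np.argmin(prof.chi2), prof.chi2.shape)
        assert (grid1[i], grid2[j]) == (175.0, 575.0)
        assert prof.chi2_min < 1e-15

    def test_threshold_at_minimum_gives_argmin_region(self, full_length_protocol):
        tit = self.make_titration(full_length_protocol)
        grid = np.array([150.0, 175.0, 200.0])
        prof = pf.chi2_profile_two_sites(tit, grid, np.array([500.0, 575.0]),
                                         threshold=0.0)
        prof2 = pf.chi2_profile_two_sites(tit, grid, np.array([500.0, 575.0]),
                                          threshold=prof.chi2_min)
        assert (175.0, 575.0) in prof2.region

    def test_region_monotone_in_threshold(self, full_length_protocol):
        tit = self.make_titration(full_length_protocol)
        grid1 = np.geomspace(50.0, 700.0, 5)
        grid2 = np.geomspace(200.0, 2000.0, 5)
        small = pf.chi2_profile_two_sites(tit, grid1, grid2, threshold=1e-4)
        large = pf.chi2_profile_two_sites(tit, grid1, grid2, threshold=1e-1)
        assert set(small.region) <= set(large.region)

    def test_threshold_below_minimum_is_empty_not_error(self, full_length_protocol):
        tit = self.make_titration(full_length_protocol)
        prof = pf.chi2_profile_two_sites(tit, np.array([100.0, 300.0]),
                                         np.array([400.0, 800.0]), threshold=1e-15)
        assert prof.region == []
        assert prof.kd1_range is None

    def test_bad_grids_rejected(self, full_length_protocol):
        tit = self.make_titration(full_length_protocol)
        with pytest.raises(ValueError):
            pf.chi2_profile_two_sites(tit, np.array([-1.0, 2.0]),
                                      np.array([1.0, 2.0]), 1.0)
        with pytest.raises(ValueError):
            pf.chi2_profile_two_sites(tit, np.array([2.0, 1.0]),
                                      np.array([1.0, 2.0]), 1.0)


class TestThermodynamics:
    def test_unit_ratio_is_zero(self):
        assert pf.ddg_ratio(1.0) == 0.0

    def test_three_fold_ratio(self):
        # R T ln 3 at 298.15 K
        assert pf.ddg_ratio(3.0, 298.15) == pytest.approx(0.651, abs=0.001)

    def test_e_fold_ratio_is_rt(self):
        assert pf.ddg_ratio(np.e, 298.15) == pytest.approx(R_KCAL * 298.15, rel=1e-12)

    def test_delta_g_standard_state(self):
        # 1 M dissociation constant -> zero standard free energy
        assert pf.delta_g(1e6, 298.15) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pf.delta_g(-1.0)
        with pytest.raises(ValueError):
            pf.ddg_ratio(0.0)
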