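import numpy as np
import pytest
from scipy.optimize import brentq

from canopyflux.leaf import (BERNACCHI_2001, FarquharParams, JarvisParams,
                             couple_leaf, farquhar_net_a, jarvis_gs,
                             leaf_energy_balance, saturation_vp,
                             scale_params_from_light, GSW_GSC_RATIO, P_ATM)


@pytest.fixture
def fp():
    return FarquharParams(60.0, 120.0, 1.5)


class TestFarquhar:
    def test_dark_respiration_limit(self, fp):
        a = farquhar_net_a(300.0, 0.0, 25.0, fp)
        assert a == pytest.approx(-1.5, abs=1e-9)
        # at another temperature, the Arrhenius-scaled R_d
        rd30 = fp.at_temperature(30.0)["Rd"]
        assert farquhar_net_a(300.0, 0.0, 30.0, fp) == pytest.approx(-rd30)

    def test_compensation_behavior(self, fp):
        gamma = fp.at_temperature(25.0)["gamma_star"]
        # gross assimilation vanishes at gamma*, so net = -Rd there
        a = farquhar_net_a(gamma, 1500.0, 25.0, fp)
        assert a == pytest.approx(-1.5, abs=1e-9)

    def test_monotone_in_ci(self, fp):
        ci = np.linspace(30.0, 1500.0, 50)
        a = farquhar_net_a(ci, 1200.0, 25.0, fp)
        assert np.all(np.diff(a) >= -1e-9)

    def test_rejects_nonpositive_ci(self, fp):
        with pytest.raises(ValueError):
            farquhar_net_a(0.0, 500.0, 25.0, fp)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FarquharParams(-1.0, 100.0, 1.0)


class TestJarvis:
    @pytest.fixture
    def jp(self):
        return JarvisParams(g_smax=0.4, K_ppfd=150.0, T_opt=27.0,
                            T_breadth=12.0, vpd0=1.5, vpd_slope=0.35)

    def test_optimal_conditions_give_gsmax(self, jp):
        gs = jarvis_gs(1500.0, 27.0, 1.0, 0.4, jp)
        assert gs == pytest.approx(0.4)

    def test_vpd_plateau_exact(self, jp):
        for vpd in (0.5, 1.0, 1.5):
            assert jp.f_vpd(vpd) == 1.0

    def test_vpd_linear_decline(self, jp):
        assert jp.f_vpd(2.0) == pytest.approx(1.0 - 0.5 * 0.35)

    def test_factors_bounded(self, jp):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p, t, v = rng.uniform(0, 3000), rng.uniform(-5, 50), \
                rng.uniform(0, 6)
            for f in (jp.f_ppfd(p), jp.f_t(t), jp.f_vpd(v)):
                assert 0.0 <= f <= 1.0


class TestCoupling:
    def test_root_residual_property(self, funcs):
        """The returned C_i satisfies the diffusion identity to 1e-6."""
        rng = np.random.default_rng(5)
        for _ in range(1000):
            ppfd = rng.uniform(20.0, 1800.0)
            tair = rng.uniform(12.0, 38.0)
            vpd = rng.uniform(0.2, 3.5)
            na = rng.uniform(1.0, 3.0)
            st = couple_leaf(ppfd, tair, vpd, funcs, N_a=na, ci_tol=1e-7)
            if st.g_s < 1e-7:
                continue
            _, fp_, _ = _leaf_params(funcs, na)
            lhs = farquhar_net_a(st.C_i, ppfd, tair, fp_)
            rhs = st.g_s / GSW_GSC_RATIO * (380.0 - st.C_i)
            assert abs(lhs - rhs) < 1e-6

    def test_large_gs_limit(self, funcs):
        big = _funcs_with_gsmax(funcs, 50.0)
        st = couple_leaf(1500.0, 27.0, 0.5, big, N_a=2.0)
        assert st.C_i == pytest.approx(380.0, abs=5.0)

    def test_closed_stomata_limit(self, funcs):
        st = couple_leaf(0.0, 25.0, 1.0, funcs, N_a=2.0)
        _, fp_, _ = _leaf_params(funcs, 2.0)
        assert st.g_s == 0.0
        assert st.A_l == pytest.approx(-fp_.at_temperature(25.0)["Rd"])
        assert st.E_l == 0.0

    def test_wue_identity(self, funcs):
        st = couple_leaf(900.0, 26.0, 1.2, funcs, N_a=2.2)
        assert st.WUE_l == st.A_l / st.E_l

    def test_textbook_constant_gs_oracle(self, funcs):
        """All Jarvis factors at 1 and energy balance off reduce the
        coupled model to the classic Farquhar + fixed-g_s solution,
        solved here independently."""
        na = 2.0
        _, fp_, gsmax = _leaf_params(funcs, na)
        sat = _funcs_with_shapes(funcs)  # factors pinned at 1
        st = couple_leaf(1500.0, sat.jarvis.T_opt, 0.5, sat, N_a=na)
        assert st.g_s == pytest.approx(gsmax)
        gc = gsmax / GSW_GSC_RATIO

        ci = brentq(lambda c: farquhar_net_a(c, 1500.0, sat.jarvis.T_opt,
                                             fp_) - gc * (380.0 - c),
                    1.0, 380.0, xtol=1e-10)
        assert st.C_i == pytest.approx(ci, abs=1e-3)

    def test_transpiration_formula(self, funcs):
        st = couple_leaf(1000.0, 25.0, 1.0, funcs, N_a=2.0)
        assert st.E_l == pytest.approx(st.g_s * 1.0 / P_ATM * 1000.0)


class TestNitrogenScaling:
    def test_equal_light_equal_params(self, funcs):
        a = scale_params_from_light(30.0, funcs)
        b = scale_params_from_light(30.0, funcs)
        assert a[0] == b[0]
        assert a[1].V_cmax25 == b[1].V_cmax25
        assert a[2] == b[2]

    def test_na_strictly_increasing_with_light(self, funcs):
        nas = [scale_params_from_light(p, funcs)[0]
               for p in (5.0, 20.0, 40.0, 55.0)]
        assert all(a < b for a, b in zip(nas, nas[1:]))

    def test_chained_linear_maps(self, funcs):
        for ppfd_d in (10.0, 30.0, 50.0):
            na, fp_, gsmax = scale_params_from_light(ppfd_d, funcs)
            na_hand = 0.025 * ppfd_d + 1.2
            assert na == pytest.approx(na_hand)
            assert fp_.V_cmax25 == pytest.approx(30.0 * na_hand + 5.0)
            assert fp_.R_d25 == pytest.approx(-0.3 * na_hand + 2.0)
            assert gsmax == pytest.approx(0.15 * na_hand + 0.05)

    def test_rejects_negative_light(self, funcs):
        with pytest.raises(ValueError):
            scale_params_from_light(-1.0, funcs)


class TestEnergyBalance:
    def test_zero_net_load_keeps_air_temperature(self):
        # absorbed equal to emission at T_air, stomata closed, dry budget
        T_air = 22.0
        absorbed = 0.97 * 5.670374419e-8 * (T_air + 273.15) ** 4
        T_leaf, resid = leaf_energy_balance(absorbed, T_air, 2.0,
                                            g_s=1e-12, rh=50.0)
        assert T_leaf == pytest.approx(T_air, abs=1e-4)
        assert abs(resid) < 0.01

    def test_monotone_in_radiation(self):
        T_air = 25.0
        loads = [380.0, 450.0, 520.0]
        temps = [leaf_energy_balance(l, T_air, 1.5, 0.2, rh=50.0)[0]
                 for l in loads]
        assert temps[0] < temps[1] < temps[2]

    def test_budget_closure_random_states(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            T_air = rng.uniform(10.0, 35.0)
            load = rng.uniform(250.0, 600.0)
            wind = rng.uniform(0.2, 5.0)
            gs = rng.uniform(0.01, 0.6)
            rh = rng.uniform(20.0, 90.0)
            try:
                _, resid = leaf_energy_balance(load, T_air, wind, gs, rh=rh)
            except RuntimeError:
                continue  # outside the sanity band
            assert abs(resid) < 0.01


def _leaf_params(funcs, na):
    from canopyflux.leaf import _params_from_na
    return _params_from_na(na, funcs)


def _funcs_with_gsmax(funcs, gsmax):
    from dataclasses import replace
    # flat gsmax line: intercept only
    return replace(funcs, gsmax_vs_na=(0.0, gsmax))


def _funcs_with_shapes(funcs):
    from dataclasses import replace
    jp = replace(funcs.jarvis, K_ppfd=1e-9, T_breadth=1e6, vpd0=2.9,
                 vpd_slope=0.0)
    return replace(funcs, jarvis=jp)
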