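"""Mechanistic rate laws: limits, identities, conservation, oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from biopbpk import compiler, engine, mechanisms as mech


def _pore_params(**kw):
    defaults = dict(L_S=0.01, L_L=0.002, sigma_S=0.6, sigma_L=0.1,
                    PS_S=0.005, PS_L=0.001, Pe_S=0.5, Pe_L=2.0)
    defaults.update(kw)
    return mech.TwoPoreParams(**defaults)


class TestTwoPoreClearance:
    def test_equal_concentrations_give_pure_convection(self):
        p = _pore_params()
        cl_s, cl_l = mech.two_pore_clearance(p, C_is=2.0, C_v=2.0)
        assert cl_s == pytest.approx(p.L_S * (1 - p.sigma_S))
        assert cl_l == pytest.approx(p.L_L * (1 - p.sigma_L))

    def test_full_exclusion_zeroes_small_pore_clearance(self):
        p = _pore_params(sigma_S=1.0, PS_S=0.0)
        cl_s, _ = mech.two_pore_clearance(p, C_is=0.5, C_v=1.0)
        assert cl_s == 0.0

    def test_small_peclet_limit_recovers_plain_diffusion(self):
        """Pe/(e^Pe - 1) -> 1, so CL -> L(1-sigma) + PS(1 - C_is/C_v)."""
        for pe in (1e-6, 1e-9, 0.0):
            p = _pore_params(Pe_S=pe)
            cl_s, _ = mech.two_pore_clearance(p, C_is=0.25, C_v=1.0)
            limit = p.L_S * (1 - p.sigma_S) + p.PS_S * (1 - 0.25)
            assert cl_s == pytest.approx(limit, rel=1e-6)
        # second-order series check: factor = 1 - Pe/2 + Pe^2/12 + O(Pe^4)
        pe = 1e-3
        series = 1 - pe / 2 + pe**2 / 12
        assert mech.peclet_factor(pe) == pytest.approx(series, rel=1e-9)

    def test_rate_and_clearance_forms_agree_when_both_defined(self):
        p = _pore_params()
        c_is, c_v = 0.3, 1.7
        cl_s, cl_l = mech.two_pore_clearance(p, c_is, c_v)
        assert mech.two_pore_rate(p, c_is, c_v) == pytest.approx((cl_s + cl_l) * c_v)

    def test_rate_form_is_finite_at_zero_vascular_concentration(self):
        p = _pore_params()
        rate = mech.two_pore_rate(p, C_is=1.0, C_v=0.0)
        assert rate < 0  # pure back-diffusion into the vascular space


class TestComputeTwoPoreParams:
    def test_full_steric_exclusion_at_small_pore(self):
        # a 150 kDa solute has a Stokes radius above a 4.5 nm small pore
        p = mech.compute_two_pore_params(150.0, lymph_flow=0.01)
        assert p.sigma_S == 1.0
        assert p.PS_S == 0.0
        assert p.Pe_S == 0.0

    def test_sigma_monotone_nondecreasing_in_mw(self):
        grid = np.geomspace(1.0, 1000.0, 60)
        for attr in ("sigma_S", "sigma_L"):
            vals = [getattr(mech.compute_two_pore_params(m, 0.01), attr) for m in grid]
            assert np.all(np.diff(vals) >= -1e-12)

    def test_ps_monotone_nonincreasing_in_mw(self):
        grid = np.geomspace(1.0, 1000.0, 60)
        for attr in ("PS_S", "PS_L"):
            vals = [getattr(mech.compute_two_pore_params(m, 0.01), attr) for m in grid]
            assert np.all(np.diff(vals) <= 1e-12)

    def test_peclet_reconstructed_from_components(self):
        p = mech.compute_two_pore_params(20.0, lymph_flow=0.02)
        assert p.Pe_S == pytest.approx(p.J_S * (1 - p.sigma_S) / p.PS_S)
        assert p.Pe_L == pytest.approx(p.J_L * (1 - p.sigma_L) / p.PS_L)
        assert p.L_S + p.L_L == pytest.approx(0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="positive"):
            mech.compute_two_pore_params(0.0, 0.01)
        with pytest.raises(ValueError, match="radius"):
            mech.compute_two_pore_params(10.0, 0.01, rS=30.0, rL=25.0)


class TestFcRn:
    def test_total_receptor_conserved_at_random_points(self):
        rng = np.random.default_rng(7)
        p = mech.FcRnParams()
        for _ in range(50):
            a = rng.uniform(0, 1e-6, 5)
            d = mech.fcrn_rhs(*a, p, v_en=1e-3)
            assert d[3] + d[4] == pytest.approx(0.0, abs=1e-25)

    def test_no_binding_gives_single_exponential_catabolism(self):
        """With kon = 0 the endosomal drug decays at CLcat/V_en."""
        p = mech.FcRnParams(Kup_va=0.0, Kup_is=0.0, kon=0.0, CLcat=2e-3)
        v_en = 1e-3

        def rhs(t, y):
            return mech.fcrn_rhs(0.0, 0.0, y[0], y[1], y[2], p, v_en)[2:5]

        sol = solve_ivp(rhs, (0, 2), [1e-9, 4e-8, 0.0], rtol=1e-10, atol=1e-20,
                        t_eval=np.linspace(0, 2, 11))
        exact = 1e-9 * np.exp(-p.CLcat / v_en * sol.t)
        np.testing.assert_allclose(sol.y[0], exact, rtol=1e-7)
        assert np.all(sol.y[2] == 0.0)  # complex never forms

    def test_one_way_binding_depletes_free_receptor(self):
        p = mech.FcRnParams(koff=0.0, krec=0.0, kon=1e7)
        d = mech.fcrn_rhs(0.0, 0.0, 1e-9, 4e-8, 0.0, p, 1e-3)
        assert d[3] < 0  # free FcRn strictly decreasing while drug is present

    def test_recycling_split(self):
        p = mech.FcRnParams(Kup_va=0.0, Kup_is=0.0, f_rec_va=0.25, krec=2.0)
        d = mech.fcrn_rhs(0.0, 0.0, 0.0, 0.0, 1e-9, p, 1e-3)
        assert d[0] == pytest.approx(0.25 * 2.0 * 1e-9)
        assert d[1] == pytest.approx(0.75 * 2.0 * 1e-9)


class TestRenal:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (mech.RenalParams(GFR=7.2, theta=0.0), 0.0),
            (mech.RenalParams(GFR=7.2, theta=1.0, fup=1.0, freab=0.0), 7.2),
            (mech.RenalParams(GFR=7.2, theta=0.8, fup=0.5, freab=1.0), 0.0),
            (mech.RenalParams(GFR=10.0, theta=0.5, fup=0.4, freab=0.25), 1.5),
        ],
    )
    def test_net_filtration_clearance(self, params, expected):
        assert mech.renal_filtration_cl(params) == pytest.approx(expected)

    def test_gsc_limits_and_monotonicity(self):
        assert mech.gsc_from_mw(1e-6) == pytest.approx(1.0, abs=1e-3)
        assert mech.gsc_from_mw(150.0) < mech.gsc_from_mw(20.0)
        grid = np.geomspace(0.1, 500.0, 80)
        vals = [mech.gsc_from_mw(m) for m in grid]
        assert np.all(np.diff(vals) <= 1e-12)
        # negligible filtration for large proteins
        assert all(mech.gsc_from_mw(m) <= mech.gsc_from_mw(59.0) for m in (60, 100, 300))
        with pytest.raises(ValueError):
            mech.gsc_from_mw(0.0)


class TestTMDD:
    def test_target_settles_at_turnover_baseline(self):
        p = mech.TMDDParams(ksyn=2e-9, kdeg=0.1, kon=1e8, koff=1.0)
        assert p.baseline == pytest.approx(2e-8)
        sol = solve_ivp(
            lambda t, y: mech.tmdd_rhs(0.0, y[0], 0.0, p)[1:2],
            (0, 400), [0.0], rtol=1e-10, atol=1e-20,
        )
        assert sol.y[0, -1] == pytest.approx(p.baseline, rel=1e-6)

    def test_no_binding_leaves_drug_untouched(self):
        p = mech.TMDDParams(ksyn=1e-9, kdeg=0.1, kon=0.0, koff=1.0)
        d_drug, _, _ = mech.tmdd_rhs(5e-8, 1e-8, 0.0, p)
        assert d_drug == 0.0

    def test_default_internalization_rates(self):
        mem = mech.TMDDParams(ksyn=1, kdeg=0.2, kon=1, koff=1, target_kind="membrane")
        sol = mech.TMDDParams(ksyn=1, kdeg=0.2, kon=1, koff=1,
                              target_kind="soluble", kel_drug=0.05)
        assert mem.internalization_rate() == 0.2
        assert sol.internalization_rate() == 0.05

    def test_matches_brute_force_euler(self):
        p = mech.TMDDParams(ksyn=1e-9, kdeg=0.1, kon=1e8, koff=0.5, kint=0.2)
        y = np.array([5e-8, p.baseline, 0.0])
        h = 1e-5
        for _ in range(2000):
            y = y + h * np.asarray(mech.tmdd_rhs(*y, p))
        sol = solve_ivp(
            lambda t, v: mech.tmdd_rhs(*v, p), (0, 2000 * h),
            [5e-8, p.baseline, 0.0], rtol=1e-12, atol=1e-24,
        )
        np.testing.assert_allclose(sol.y[:, -1], y, rtol=1e-3)

    def test_target_mediated_fraction_saturates_with_dose(self):
        """The target-route share of elimination falls as the dose rises."""
        p = mech.TMDDParams(ksyn=1e-9, kdeg=0.1, kon=1e9, koff=0.1, kint=0.5)
        graph = mech.tmdd_subgraph(p)
        graph.add_parameter("kel", default=0.05)
        graph.add_reaction("el", "kel*Drug", substrates=[("Drug", 1)])
        model = compiler.compile_graph(graph)

        def tm_fraction(dose):
            res = engine.simulate(
                model, 200.0, overrides={"Drug": dose},
                options=engine.SolverOptions(rtol=1e-10, atol=1e-22),
            )
            # integrate both elimination routes over the trajectory
            t = res.times
            kint_flux = np.trapezoid(0.5 * res.state("Complex"), t)
            kel_flux = np.trapezoid(0.05 * res.state("Drug"), t)
            return kint_flux / (kint_flux + kel_flux)

        assert tm_fraction(1e-6) < tm_fraction(1e-8)

    def test_linear_regime_clearance_is_dose_independent(self):
        """Far below saturation the TMDD route behaves linearly (<1% shift)."""
        p = mech.TMDDParams(ksyn=1e-9, kdeg=0.1, kon=1e6, koff=10.0, kint=0.5)
        graph = mech.tmdd_subgraph(p)
        model = compiler.compile_graph(graph)
        opts = engine.SolverOptions(rtol=1e-10, atol=1e-24)
        lo = engine.simulate(model, 50.0, overrides={"Drug": 1e-12}, options=opts)
        hi = engine.simulate(model, 50.0, overrides={"Drug": 2e-12}, options=opts)
        ratio = hi.state("Drug")[1:] / lo.state("Drug")[1:]
        assert np.all(np.abs(ratio - 2.0) < 0.01 * 2.0)


class TestBinding:
    def test_no_binding_and_equal_albumin_limits(self):
        assert mech.fraction_unbound_interstitial(mech.BindingParams(fu_p=1.0)) == 1.0
        p = mech.BindingParams(fu_p=0.3, alb_ratio_is=1.0)
        assert mech.fraction_unbound_interstitial(p) == pytest.approx(0.3)

    def test_interstitial_fraction_against_equilibrium_root(self):
        """Closed form vs numeric solve of 1/fu = 1 + R*(1/fu_p - 1)."""
        p = mech.BindingParams(fu_p=0.1, alb_ratio_is=0.5)
        fu_is = mech.fraction_unbound_interstitial(p)
        root = brentq(lambda f: 1.0 / f - (1.0 + 0.5 * (1.0 / 0.1 - 1.0)), 1e-6, 1.0)
        assert fu_is == pytest.approx(root, rel=1e-10)
        assert fu_is >= p.fu_p

    def test_per_organ_ratio_lookup(self):
        p = mech.BindingParams(fu_p=0.2, alb_ratio_is={"li": 0.4, "mu": 0.8})
        assert mech.fraction_unbound_interstitial(p, "li") > 0.2
        with pytest.raises(ValueError, match="organ required"):
            mech.fraction_unbound_interstitial(p)


class TestDoseConversion:
    def test_unit_arithmetic(self):
        assert mech.dose_to_moles(1.0, 70.0, 150.0) == pytest.approx(70.0 / 1.5e8)
        assert mech.dose_to_moles(0.0, 70.0, 150.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mech.dose_to_moles(1.0, 0.0, 150.0)
        with pytest.raises(ValueError):
            mech.dose_to_moles(-1.0, 70.0, 150.0)
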