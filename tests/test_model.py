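"""Closed forms, PDE simulator, fitting and predictions of the feedback model."""

import math

import numpy as np
import pytest

from ringflow import model as fm

from conftest import ode_ring_size


class TestClosedForms:
    def test_half_closure_origin(self, params):
        # the time origin is defined by Rbar(0) = 1/2 for any Rbar_ini
        for rini in (0.8, 1.1, 2.0):
            p = fm.ModelParams.from_timescale(79.0, rbar_ini=rini)
            assert fm.ring_size_closed_form(p, 0.0) == pytest.approx(0.5, abs=1e-12)

    def test_ring_size_matches_ode_oracle(self, params):
        # closed form vs independent numerical integration of the rate law
        for tbar in (-1.0, 0.5, 1.0):
            assert fm.ring_size_closed_form(params, tbar) == pytest.approx(
                ode_ring_size(1.1, tbar), rel=1e-7
            )
        assert fm.ring_size_closed_form(params, 1.0) == pytest.approx(0.129, abs=5e-4)

    def test_per_length_rate_at_origin(self, params):
        assert fm.per_length_constriction_rate(params, 0.0) == pytest.approx(
            math.log(2.2), rel=1e-12
        )

    def test_myosin_efold_and_doubling(self, params):
        m0 = fm.mring_closed_form(params, 0.0)
        assert fm.mring_closed_form(params, params.tau) / m0 == pytest.approx(math.e)
        t_double = params.tau * math.log(2.0)
        assert fm.mring_closed_form(params, t_double) / m0 == pytest.approx(2.0)

    def test_closed_forms_satisfy_rate_laws(self, params):
        # d(Rbar)/dtbar = −ln(2 Rbar_ini) e^tbar Rbar and dM/dt = α m_rho M
        tb = np.linspace(-1.5, 1.2, 40)
        h = 1e-5
        drdt = (
            fm.ring_size_closed_form(params, tb + h)
            - fm.ring_size_closed_form(params, tb - h)
        ) / (2 * h)
        expected = -math.log(2.2) * np.exp(tb) * fm.ring_size_closed_form(params, tb)
        assert np.allclose(drdt, expected, atol=1e-5)

        t = np.linspace(0.0, 150.0, 20)
        dmdt = (fm.mring_closed_form(params, t + h) - fm.mring_closed_form(params, t - h)) / (2 * h)
        assert np.allclose(dmdt, params.alpha * params.m_rho * fm.mring_closed_form(params, t), rtol=1e-7)

    def test_equal_size_implies_equal_dimensionless_rate(self):
        # two trajectories with equal Rbar_ini, different tau: at equal Rbar
        # the dimensionless per-unit-length rate −(1/Rbar)dRbar/dtbar agrees
        p1 = fm.ModelParams.from_timescale(60.0)
        p2 = fm.ModelParams.from_timescale(110.0)
        for rbar in (0.7, 0.5, 0.2):
            tb1 = math.log(math.log(p1.rbar_ini / rbar) / math.log(2 * p1.rbar_ini))
            tb2 = math.log(math.log(p2.rbar_ini / rbar) / math.log(2 * p2.rbar_ini))
            r1 = fm.per_length_constriction_rate(p1, tb1)
            r2 = fm.per_length_constriction_rate(p2, tb2)
            assert r1 == pytest.approx(r2, abs=1e-6)

    def test_component_closed_form(self, params):
        flat = fm.ComponentParams(c_rho=0.0, c0_ring=3.0)
        tb = np.linspace(-1, 1, 7)
        assert np.allclose(fm.component_closed_form(params, flat, tb), 3.0)
        comp = fm.ComponentParams(c_rho=0.4, c0_ring=2.0)
        assert fm.component_closed_form(params, comp, 0.0) == pytest.approx(2.0)
        # the myosin special case: c_rho = m_rho with zero baseline
        myo = fm.ComponentParams(
            c_rho=params.m_rho,
            c0_ring=params.alpha * params.m_rho / params.beta * math.log(2.2),
        )
        assert myo.c_ring_base(params) == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(
            fm.component_closed_form(params, myo, tb),
            fm.mring_closed_form(params, tb * params.tau),
        )

    def test_vflow_edge_speed(self, params):
        # v_flow = alpha * M_ring / 2 per side
        tb = 0.3
        expected = params.alpha * fm.mring_closed_form(params, tb * params.tau) / 2.0
        assert fm.vflow_closed_form(params, tb) == pytest.approx(expected)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(fm.InvalidParameterError):
            fm.ModelParams(alpha=-1.0, beta=1.0, m_rho=1.0)
        with pytest.raises(fm.InvalidParameterError):
            fm.ModelParams(alpha=1.0, beta=1.0, m_rho=1.0, rbar_ini=0.4)
        with pytest.raises(fm.InvalidParameterError):
            fm.ModelParams.from_timescale(-5.0)

    def test_tau_identity(self, params):
        assert params.tau * params.alpha * params.m_rho == pytest.approx(1.0, abs=1e-12)


class TestPDE:
    def test_zero_initial_state_is_static(self, params):
        states = fm.pde_simulate(params, 0.0, t_end=50.0, dx=0.1)
        assert states[-1].m_ring == 0.0
        assert np.all(states[-1].v == 0.0)

    def test_exponential_growth_matches_closed_form(self, params):
        w = params.zone_half_width
        states = fm.pde_simulate(params, params.m_rho, t_end=2 * params.tau, dx=w / 200)
        exact = states[0].m_ring * math.exp(states[-1].t / params.tau)
        assert abs(states[-1].m_ring - exact) / exact < 0.01

    def test_first_order_convergence(self, params):
        w = params.zone_half_width
        errs = []
        for n in (25, 50, 100):
            states = fm.pde_simulate(params, params.m_rho, t_end=params.tau, dx=w / n)
            exact = states[0].m_ring * math.exp(states[-1].t / params.tau)
            errs.append(abs(states[-1].m_ring - exact) / exact)
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[2] > 2.5  # roughly first order over 4x refinement

    def test_edge_inflow_speed(self, params):
        states = fm.pde_simulate(params, params.m_rho, t_end=30.0, dx=0.05)
        st = states[-1]
        assert st.edge_speed == pytest.approx(params.alpha * st.m_ring / 2.0)

    def test_cfl_violation_raises_before_stepping(self, params):
        with pytest.raises(fm.CFLError):
            fm.pde_simulate(params, 100.0 * params.m_rho, t_end=10.0, dx=0.05, dt=5.0)


class TestFitting:
    def _clean_series(self, params, n=24):
        that = np.linspace(0.05, 0.95, n)
        k = 2.7
        t_half = 0.5
        tbar = k * (that - t_half)
        myosin = fm.mring_closed_form(params, tbar * params.tau)
        rate = fm.per_length_constriction_rate(params, tbar, dimensionless=False)
        rbar = fm.ring_size_closed_form(params, tbar)
        return that, tbar, myosin, rate, rbar, k, t_half

    def test_noiseless_feedback_fit_is_exact(self, params):
        that, tbar, myosin, rate, rbar, k, t_half = self._clean_series(params)
        fit = fm.fit_feedback(
            {"myosin": (that, myosin), "constriction_rate": (that, rate)},
            rbar=(that, rbar),
            t_ck=k * params.tau,
        )
        assert fit.k == pytest.approx(k, rel=1e-4)
        assert fit.t_hat_half == pytest.approx(t_half, abs=1e-4)
        assert fit.tau == pytest.approx(params.tau, rel=1e-4)
        assert fit.beta() == pytest.approx(params.beta, rel=1e-3)
        assert fit.ssr < 1e-8

    def test_retention_fit_exact_on_retention_data(self, params):
        that, tbar, _, _, rbar, _, _ = self._clean_series(params)
        y = 1.5 + 4.0 / rbar
        fit = fm.fit_retention({"c": (that, y)}, rbar=(that, rbar))
        assert fit.baselines["c"] == pytest.approx(1.5, abs=1e-9)
        assert fit.amplitudes["c"] == pytest.approx(4.0, rel=1e-9)
        assert fit.ssr == pytest.approx(0.0, abs=1e-12)

    def test_flat_series_not_identifiable(self, params):
        that = np.linspace(0.1, 0.9, 10)
        with pytest.raises(fm.FitFailureError):
            fm.fit_feedback({"flat": (that, np.ones(10))})

    def test_compare_models_prefers_generating_model(self, params):
        that, tbar, myosin, _, rbar, k, _ = self._clean_series(params)
        rng = np.random.default_rng(0)
        noisy = myosin * (1 + rng.normal(0, 0.05, myosin.shape))
        cmp_fb = fm.compare_models({"myosin": (that, noisy)}, rbar=(that, rbar))
        assert cmp_fb.preferred == "feedback"
        ret = (2.0 / rbar) * (1 + rng.normal(0, 0.05, rbar.shape))
        cmp_rt = fm.compare_models({"myosin": (that, ret)}, rbar=(that, rbar))
        assert cmp_rt.preferred == "retention"


class TestPredictions:
    def test_bleach_nothing_gives_zero_difference(self, params):
        pred = fm.predict_bleach(params, -0.6, model="feedback", bleach_fraction=0.0)
        assert np.allclose(pred["difference"], 0.0)
        assert np.allclose(pred["bleached"], pred["control"])

    def test_feedback_difference_constant(self, params):
        pred = fm.predict_bleach(params, -0.6, model="feedback")
        assert np.ptp(pred["difference"]) == pytest.approx(0.0, abs=1e-12)
        # bleached ring re-accumulates at the control rate
        assert np.allclose(np.diff(pred["bleached"]), np.diff(pred["control"]))

    def test_retention_difference_scales_inversely_with_ring_size(self, params):
        tb_b = -0.6
        rb_b = float(fm.ring_size_closed_form(params, tb_b))
        # find the time where the ring has halved from the bleach point
        tb_half = math.log(
            math.log(params.rbar_ini / (rb_b / 2)) / math.log(2 * params.rbar_ini)
        )
        pred = fm.predict_bleach(params, tb_b, model="retention", tbar=[tb_b, tb_half])
        assert pred["difference"][1] / pred["difference"][0] == pytest.approx(2.0, rel=1e-9)

    def test_laser_cut_reference_chain(self):
        exp = fm.laser_cut_expectation(35.0, 7.0, 0.22, 13.0)
        assert exp.plane_gain_um2 == pytest.approx(17.5)
        assert exp.radius_decrement_um == pytest.approx(0.4, abs=0.01)
        assert exp.rate_increment_um_s == pytest.approx(0.03, abs=0.001)
        assert exp.expected_rate_um_s == pytest.approx(0.25, abs=0.001)

    def test_laser_cut_zero_opening(self):
        exp = fm.laser_cut_expectation(0.0, 7.0, 0.22, 13.0)
        assert exp.plane_gain_um2 == 0.0
        assert exp.expected_rate_um_s == 0.22

    def test_laser_cut_doubled_opening(self):
        exp = fm.laser_cut_expectation(70.0, 7.0, 0.22, 13.0)
        assert exp.plane_gain_um2 == pytest.approx(35.0)
        assert exp.radius_decrement_um == pytest.approx(35.0 / (2 * math.pi * 7.0))
        assert exp.rate_increment_um_s == pytest.approx(0.0612, abs=0.0005)
        assert exp.expected_rate_um_s == pytest.approx(0.281, abs=0.001)
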