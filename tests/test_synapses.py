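"""Receptor kinetics, short-term plasticity, gap junctions, dopamine gains."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bgsim.params import DopamineState, PlasticityParams, synapse_tables
from bgsim.synapses import (GapJunction, PlasticityState, ReceptorKinetics,
                            decay_plasticity, dopamine_scale_current,
                            gap_step, nmda_block, plasticity_event,
                            steady_state_scale, synaptic_current)

GABA = ReceptorKinetics("GABA_A", -80.0, 5.2)
AMPA = ReceptorKinetics("AMPA", 0.0, 6.0)


class TestSynapticCurrent:
    def test_zero_before_arrival(self):
        assert synaptic_current(4.9, 5.0, 10.0, AMPA, -60.0) == 0.0

    def test_zero_at_reversal_potential(self):
        assert synaptic_current(5.0, 5.0, 10.0, GABA, -80.0) == 0.0

    def test_magnesium_block_at_zero_mv(self):
        assert nmda_block(0.0) == pytest.approx(1.0 / 1.28)

    def test_exponential_decay_matches_dense_euler(self):
        # closed-form event conductance vs dense integration of the ODE
        tau, G = 6.0, 3.0
        dt = 1e-4
        t = np.arange(0, 30.0, dt)
        g_dense = np.empty_like(t)
        g = G
        for i in range(t.size):
            g_dense[i] = g
            g -= dt * g / tau
        g_closed = G * np.exp(-t / tau)
        assert np.max(np.abs(g_dense - g_closed) / G) < 1e-4

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            ReceptorKinetics("GABA_A", -40.0, 5.0)
        with pytest.raises(ValueError):
            ReceptorKinetics("AMPA", -70.0, 5.0)


class TestPlasticity:
    def test_first_event_from_rest_release(self):
        # u <- u + U(1-u) then release u*x: 0.5 -> 0.75, scale 0.75
        st_, scale = plasticity_event(PlasticityState(u_plus=0.5, x_minus=1.0),
                                      PlasticityParams(U=0.5, tau_f=100.0,
                                                       tau_d=100.0,
                                                       mode="facilitating"))
        assert scale == pytest.approx(0.75)
        assert st_.x_minus == pytest.approx(0.25)

    def test_zero_tau_f_pins_utilization(self):
        p = PlasticityParams(U=0.3, tau_f=0.0, tau_d=200.0, mode="depressing")
        st_ = decay_plasticity(PlasticityState(u_plus=0.9, x_minus=0.5), p, 50.0)
        assert st_.u_plus == pytest.approx(0.3)

    def test_steady_state_matches_conductance_ratio_table(self):
        # depressing SNr afferents settle at the shipped G/G0 ratios
        tabs = synapse_tables()["projections"]
        for name, rate in (("STN-SNr", 10.0), ("GPe-SNr", 30.0)):
            c = tabs[name]
            p = PlasticityParams(**{k: c["plasticity"][k]
                                    for k in ("U", "tau_f", "tau_d", "mode")})
            assert steady_state_scale(rate, p) == pytest.approx(
                c["G"] / c["G0"], rel=0.01)

    def test_depressing_scale_non_increasing_in_rate(self):
        c = synapse_tables()["projections"]["STN-SNr"]["plasticity"]
        p = PlasticityParams(U=c["U"], tau_f=c["tau_f"], tau_d=c["tau_d"],
                             mode="depressing")
        scales = [steady_state_scale(f, p) for f in np.linspace(1, 60, 30)]
        assert all(b <= a + 1e-12 for a, b in zip(scales, scales[1:]))

    def test_facilitating_scale_non_decreasing_at_low_rates(self):
        for name in ("SD1-SNr", "SD2-GPe"):
            c = synapse_tables()["projections"][name]["plasticity"]
            p = PlasticityParams(U=c["U"], tau_f=c["tau_f"], tau_d=c["tau_d"],
                                 mode="facilitating")
            scales = [steady_state_scale(f, p) for f in np.linspace(1, 10, 10)]
            assert all(b >= a - 1e-12 for a, b in zip(scales, scales[1:]))

    def test_static_limit_reproduces_event_for_event(self):
        # U -> 1, tau_f -> 0, tau_d -> 0: every event releases full G
        p = PlasticityParams(U=1.0 - 1e-12, tau_f=0.0, tau_d=1e-9,
                             mode="depressing")
        st_ = PlasticityState(u_plus=p.U, x_minus=1.0)
        for _ in range(5):
            st_, scale = plasticity_event(st_, p)
            assert scale == pytest.approx(1.0)
            st_ = decay_plasticity(st_, p, 10.0)

    @given(U=st.floats(0.01, 0.99), n=st.integers(1, 50),
           gap=st.floats(0.1, 500.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_state_bounds_invariant(self, U, n, gap):
        p = PlasticityParams(U=U, tau_f=50.0, tau_d=200.0, mode="facilitating")
        s = PlasticityState(u_plus=U, x_minus=1.0)
        for _ in range(n):
            s, scale = plasticity_event(s, p)
            assert 0.0 <= s.u_plus <= 1.0
            assert 0.0 <= s.x_minus <= 1.0
            assert 0.0 <= scale <= 1.0
            s = decay_plasticity(s, p, gap)


class TestGapJunction:
    def test_equilibrium_currents_vanish(self):
        j = GapJunction(0, 1, g_gap=0.5, tau_gap=5.0, v_gap=-60.0)
        I_i, I_j, vg = gap_step(j, -60.0, -60.0, 0.1)
        assert I_i == 0.0 and I_j == 0.0 and vg == pytest.approx(-60.0)

    def test_symmetric_opposite_currents(self):
        j = GapJunction(0, 1, g_gap=0.5, tau_gap=5.0, v_gap=-60.0)
        I_i, I_j, _ = gap_step(j, -40.0, -80.0, 0.1)
        assert I_i == pytest.approx(-I_j)
        assert I_i < 0 < I_j

    def test_step_response_time_constant(self):
        # with fixed (v_i+v_j)/2, v_gap relaxes exponentially at tau_gap/2
        tau, dt, vbar = 5.0, 1e-3, -50.0
        j = GapJunction(0, 1, g_gap=0.5, tau_gap=tau, v_gap=-70.0)
        t = 0.0
        while t < tau / 2.0:
            _, _, vg = gap_step(j, vbar, vbar, dt)
            j.v_gap = vg
            t += dt
        expected = vbar + (-70.0 - vbar) * np.exp(-1.0)
        assert j.v_gap == pytest.approx(expected, abs=0.05)


class TestDopamineGains:
    def test_zero_dopamine_identity(self):
        base = {"ampa": 10.0, "nmda": 5.0, "gaba": -3.0}
        da = DopamineState(0.0, 0.0)
        for pop in ("MSN_D1", "MSN_D2", "FSI", "STN", "GPe"):
            assert dopamine_scale_current(pop, base, da) == base

    def test_d1_nmda_potentiation(self):
        out = dopamine_scale_current("MSN_D1", {"nmda": 1.0},
                                     DopamineState(0.3, 0.3))
        assert out["nmda"] == pytest.approx(1.15)

    def test_stn_glutamate_halved_at_full_depletion_reversal(self):
        out = dopamine_scale_current("STN", {"ampa": 1.0, "nmda": 1.0,
                                             "gaba": 1.0},
                                     DopamineState(1.0, 1.0))
        assert out["ampa"] == pytest.approx(0.5)
        assert out["nmda"] == pytest.approx(0.5)
        assert out["gaba"] == pytest.approx(0.5)
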