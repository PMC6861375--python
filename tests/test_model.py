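"""Unit tests for the ionic/synaptic reference functions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ratephase as rp
from ratephase.model import membrane_derivative, synaptic_current, synaptic_pulse
from ratephase.params import CellParams, SynapseParams


class TestSynapticPulse:
    def test_zero_before_delay(self, syn):
        for t in (-5.0, 0.0, 0.05, syn.tau_d - 1e-9):
            assert synaptic_pulse(t, 0.0, syn) == 0.0

    def test_peak_is_exactly_one_at_closed_form_time(self, syn):
        assert synaptic_pulse(syn.t_peak, 0.0, syn) == pytest.approx(1.0, abs=1e-9)

    def test_supremum_over_time_is_one(self, syn):
        t = np.linspace(0.0, 20.0, 200001)
        vals = synaptic_pulse(t, 0.0, syn)
        assert vals.max() <= 1.0 + 1e-9
        assert vals.max() == pytest.approx(1.0, abs=1e-6)

    def test_value_one_ms_after_spike_matches_direct_evaluation(self, syn):
        # independent scalar evaluation of the printed formula
        x_peak = syn.tau_s * syn.tau_f * math.log(syn.tau_s / syn.tau_f) / (
            syn.tau_s - syn.tau_f
        )
        norm = math.exp(-x_peak / syn.tau_s) - math.exp(-x_peak / syn.tau_f)
        lag = 1.0 - syn.tau_d
        expected = (math.exp(-lag / syn.tau_s) - math.exp(-lag / syn.tau_f)) / norm
        got = synaptic_pulse(1.0, 0.0, syn)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.9892118205617496, abs=1e-12)

    def test_never_fired_neuron_contributes_zero(self, syn):
        assert synaptic_pulse(100.0, -np.inf, syn) == 0.0

    def test_degenerate_time_constants_rejected(self):
        with pytest.raises(ValueError):
            SynapseParams(tau_s=0.3, tau_f=0.3)

    @settings(derandomize=True, max_examples=50)
    @given(
        lag=st.floats(-5.0, 50.0),
        tau_s=st.floats(1.0, 10.0),
        tau_f=st.floats(0.05, 0.9),
    )
    def test_bounded_in_unit_interval(self, lag, tau_s, tau_f):
        syn = SynapseParams(tau_s=tau_s, tau_f=tau_f)
        v = float(synaptic_pulse(lag, 0.0, syn))
        assert 0.0 <= v <= 1.0 + 1e-12


class TestSynapticCurrent:
    def test_no_presynaptic_activity_gives_zero(self, syn):
        out = synaptic_current(-60.0, np.zeros(5), np.ones(5), np.ones(5, bool), syn)
        assert out == 0.0

    def test_zero_driving_force_at_excitatory_reversal(self, syn):
        out = synaptic_current(
            syn.e_e, np.ones(4), np.ones(4), np.ones(4, bool), syn
        )
        assert out == 0.0

    def test_single_excitatory_edge_hand_value(self, syn):
        # one edge at peak pulse, 50 mV driving force, w_e = 0.02
        out = synaptic_current(
            syn.e_e - 50.0, np.array([1.0]), np.array([1]), np.array([True]), syn
        )
        assert out == pytest.approx(0.02 * 50.0)

    def test_mismatched_lengths_rejected(self, syn):
        with pytest.raises(ValueError):
            synaptic_current(-60.0, np.zeros(3), np.ones(4), np.ones(4, bool), syn)


def _hand_derivative(state, i_syn, i_ext, cell):
    """Independent term-by-term evaluation of the membrane equation."""
    v = float(state.v[0])
    g = cell.gating
    m = 1.0 / (1.0 + math.exp(-(v - g.m_vhalf) / g.m_k))
    i_na = cell.g_na * m**3 * float(state.h[0]) * (v - cell.e_na)
    i_kdr = cell.g_kdr * float(state.n[0]) ** 4 * (v - cell.e_k)
    i_ks = cell.g_ks * float(state.s[0]) * (v - cell.e_k)
    i_l = cell.g_l * (v - cell.e_l)
    return (i_syn + i_ext - i_na - i_kdr - i_ks - i_l) / cell.c_m


class TestMembraneDerivative:
    def test_matches_term_by_term_oracle(self, cell15):
        st_ = rp.NeuronState(v=-47.3, h=0.6, n=0.21, s=0.33, t_last_spike=-np.inf)
        d = membrane_derivative(st_, 0.7, -0.2, cell15)
        assert d.v[0] == pytest.approx(_hand_derivative(st_, 0.7, -0.2, cell15),
                                       rel=1e-12)

    def test_slow_potassium_term_vanishes_at_zero_conductance(self, cell0):
        base = dict(v=-50.0, h=0.5, n=0.3, t_last_spike=-np.inf)
        d1 = membrane_derivative(rp.NeuronState(s=0.1, **base), 0.0, 0.0, cell0)
        d2 = membrane_derivative(rp.NeuronState(s=0.9, **base), 0.0, 0.0, cell0)
        assert d1.v[0] == d2.v[0]

    def test_constructed_fixed_point_has_zero_voltage_derivative(self, cell15):
        st_ = rp.NeuronState(v=-55.0, h=0.4, n=0.25, s=0.2, t_last_spike=-np.inf)
        i_hold = -_hand_derivative(st_, 0.0, 0.0, cell15) * cell15.c_m
        d = membrane_derivative(st_, 0.0, i_hold, cell15)
        assert d.v[0] == pytest.approx(0.0, abs=1e-12)

    def test_gating_derivatives_vanish_at_steady_state(self, cell15):
        v = -48.0
        g = cell15.gating
        st_ = rp.NeuronState(v=v, h=g.h_inf(v), n=g.n_inf(v), s=g.s_inf(v),
                             t_last_spike=-np.inf)
        d = membrane_derivative(st_, 0.0, 0.0, cell15)
        for x in (d.h, d.n, d.s):
            assert abs(float(x[0])) < 1e-14

    def test_raising_gks_hyperpolarizes_above_e_k(self, cell0):
        st_ = rp.NeuronState(v=-50.0, h=0.5, n=0.3, s=0.4, t_last_spike=-np.inf)
        dv = [
            float(membrane_derivative(st_, 0.0, 0.0, cell0.with_gks(g)).v[0])
            for g in (0.0, 0.5, 1.0, 1.5)
        ]
        assert all(a > b for a, b in zip(dv, dv[1:]))

    def test_gating_variables_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            rp.NeuronState(v=-60.0, h=1.2, n=0.1, s=0.1, t_last_spike=-np.inf)


class TestJittedDerivativeAgainstReference:
    """The integrator's compiled stage derivative must agree with the
    readable reference implementation (tabulated gating allows ~1e-5)."""

    def test_cross_check_on_random_states(self, cell15, syn, rng):
        from ratephase.simulator import _cell_vec, _deriv, _gating_table, _syn_vec

        cp, sp, tab = _cell_vec(cell15), _syn_vec(syn), _gating_table(cell15)
        for _ in range(50):
            v = rng.uniform(-90.0, 40.0)
            h, n, s = rng.uniform(0.0, 1.0, 3)
            ge, gi = rng.uniform(0.0, 3.0, 2)
            iext = rng.uniform(-2.0, 2.0)
            i_syn = syn.w_e * ge * (syn.e_e - v) + syn.w_i * gi * (syn.e_i - v)
            st_ = rp.NeuronState(v=v, h=h, n=n, s=s, t_last_spike=-np.inf)
            ref = membrane_derivative(st_, i_syn, iext, cell15)
            dv, dh, dn, ds = _deriv(v, h, n, s, ge, gi, iext, cp, cell15.tau_s,
                                    sp, tab)
            assert dv == pytest.approx(float(ref.v[0]), rel=1e-4, abs=2e-4)
            assert dh == pytest.approx(float(ref.h[0]), rel=1e-4, abs=2e-6)
            assert dn == pytest.approx(float(ref.n[0]), rel=1e-4, abs=2e-6)
            assert ds == pytest.approx(float(ref.s[0]), rel=1e-4, abs=2e-6)


class TestParams:
    def test_default_file_holds_reference_constants(self, cell0, syn):
        assert cell0.tau_s == 75.0
        assert cell0.c_m == 1.0
        assert (syn.tau_d, syn.tau_s, syn.tau_f) == (0.08, 3.0, 0.3)
        assert syn.w_e == syn.w_i == 0.02

    def test_gks_outside_sweep_range_rejected(self, cell0):
        with pytest.raises(ValueError):
            cell0.with_gks(1.6)
        with pytest.raises(ValueError):
            cell0.with_gks(-0.1)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            CellParams(g_na=-1.0)
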