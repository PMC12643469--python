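"""Model core: registry structure, parameter-space contracts, gating
templates against independently coded scalar formulas, current/RHS identities
and the analytic steady-state I-V against a time-domain clamp oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epgan import datagen as dg
from epgan import hh_core as hh
from epgan import protocols as pr
from conftest import make_leak_only

V_GRID = np.arange(-120.0, 50.1, 10.0)


class TestRegistryStructure:
    def test_channel_inventory(self, registry):
        ions = [c.ion for c in registry.channels]
        assert len(registry.channels) == 16
        assert ions.count("K") == 11
        assert ions.count("Ca") == 3
        assert ions.count("leak") == 1
        assert ions.count("Na-leak") == 1

    def test_gate_and_state_counts(self, registry):
        assert registry.n_gates == 25  # +V -> 26 ODE states / initial conditions

    def test_coupled_gates_resolve_to_cav_channels(self, registry):
        coupled = [
            g for c in registry.channels for g in c.gates
            if g.ss_template == "cav_coupled"
        ]
        assert coupled, "registry must contain calcium-coupled gates"
        for g in coupled:
            assert registry.channel(g.coupled_to).ion == "Ca"


class TestParameterSpace:
    def test_trainable_counts_by_mode(self, space_small, space_large):
        assert len(space_small) == len(space_large) == 175
        assert space_large.n_trainable == 175
        assert space_small.n_trainable == 47
        frozen = ~space_small.trainable
        assert frozen.sum() == 128
        assert all(
            space_small.entries[i].group == "kinetics" for i in np.nonzero(frozen)[0]
        )

    def test_kinetics_bounds_are_baseline_pm_50pct(self, space_large):
        for e in space_large.entries:
            if e.group == "kinetics":
                assert e.min == pytest.approx(e.default - 0.5 * abs(e.default))
                assert e.max == pytest.approx(e.default + 0.5 * abs(e.default))

    def test_bounds_contain_defaults(self, space_large):
        assert np.all(space_large.lower <= space_large.defaults)
        assert np.all(space_large.defaults <= space_large.upper)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_normalization_round_trip_is_identity(self, seed):
        space = hh.build_parameter_space("large")
        rng = np.random.default_rng(seed)
        v = rng.uniform(space.lower, space.upper)
        np.testing.assert_allclose(space.denormalize(space.normalize(v)), v, atol=1e-9)
        z = space.normalize(v)
        assert np.all(z >= -1 - 1e-12) and np.all(z <= 1 + 1e-12)

    def test_assemble_rejects_unknown_and_out_of_bounds(self, space_small):
        with pytest.raises(hh.ConfigError, match="unknown"):
            hh.assemble_parameter_vector(space_small, {"no_such_param": 1.0})
        with pytest.raises(hh.ConfigError, match="out of bounds"):
            hh.assemble_parameter_vector(space_small, {"C_m": 1e6})

    def test_assemble_defaults(self, space_small):
        pv = hh.assemble_parameter_vector(space_small)
        np.testing.assert_array_equal(pv.values, space_small.defaults)


class TestGating:
    def test_boltzmann_half_activation_and_saturation(self, registry, default_params):
        ch = registry.channel("SHL1")
        gate = ch.gates[0]
        vh = default_params["SHL1_m_vhalf"]
        assert hh.gating_steady_state(vh, gate, default_params) == pytest.approx(0.5)
        assert hh.gating_steady_state(1e4, gate, default_params) == pytest.approx(1.0)
        h_gate = ch.gates[1]  # inactivation: decreasing in V
        assert hh.gating_steady_state(1e4, h_gate, default_params) == pytest.approx(0.0)

    def test_steady_state_matches_scalar_formula(self, registry, default_params):
        """Vectorized template evaluation vs an independently coded scalar
        Boltzmann, on the SHL1 activation gate."""
        gate = registry.channel("SHL1").gates[0]
        vh, k = default_params["SHL1_m_vhalf"], default_params["SHL1_m_k"]
        for V in (-80.0, -40.0, 0.0):
            expected = 1.0 / (1.0 + np.exp(-(V - vh) / k))
            assert hh.gating_steady_state(V, gate, default_params) == pytest.approx(
                expected, rel=1e-12
            )

    def test_monotonicity_of_sigmoid_gates(self, registry, default_params):
        for c in registry.channels:
            for g in c.gates:
                if g.ss_template not in ("boltzmann", "boltzmann_floor"):
                    continue
                x = hh.gating_steady_state(V_GRID, g, default_params)
                diffs = np.diff(x)
                if g.kind == "activation" and g.ss_template == "boltzmann":
                    assert np.all(diffs >= 0)
                if g.kind == "inactivation":
                    assert np.all(diffs <= 0)

    def test_constant_tau_is_voltage_independent(self, registry, default_params):
        gate = registry.channel("SHK1").gates[1]  # inactivation with constant tau
        t1 = hh.gating_time_constant(-80.0, gate, default_params)
        t2 = hh.gating_time_constant(0.0, gate, default_params)
        assert t1 == t2 > 0

    def test_bell_tau_peak_value(self, registry, default_params):
        gate = registry.channel("SHL1").gates[0]
        vp = default_params["SHL1_m_v_peak"]
        expected = default_params["SHL1_m_tau_min"] + default_params["SHL1_m_tau_amp"]
        assert hh.gating_time_constant(vp, gate, default_params) == pytest.approx(expected)

    def test_tau_grid_matches_scalar_formula_and_is_positive(self, registry, default_params):
        gate = registry.channel("EXP2").gates[0]
        tmn = default_params["EXP2_m_tau_min"]
        amp = default_params["EXP2_m_tau_amp"]
        vp = default_params["EXP2_m_v_peak"]
        w = default_params["EXP2_m_v_width"]
        got = hh.gating_time_constant(V_GRID, gate, default_params)
        expected = np.array([tmn + amp * np.exp(-(((V - vp) / w) ** 2)) for V in V_GRID])
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        for c in registry.channels:
            for g in c.gates:
                assert np.all(hh.gating_time_constant(V_GRID, g, default_params) > 0)


class TestCurrentsAndRHS:
    def test_zero_current_at_reversal(self, registry, default_params):
        for c in registry.channels:
            E = default_params[c.reversal]
            gates = np.full(len(c.gates), 0.7)
            assert hh.channel_current(c, E, gates, default_params) == 0.0

    def test_zero_gate_zeroes_current(self, registry, default_params):
        c = registry.channel("SHL1")
        gates = np.array([0.0, 0.9, 0.9])
        assert hh.channel_current(c, 0.0, gates, default_params) == 0.0

    def test_leak_current_linear_form(self, registry, space_small):
        pv = hh.assemble_parameter_vector(space_small, {"Leak_g": 2.0, "E_L": -70.0})
        leak = registry.channel("Leak")
        assert hh.channel_current(leak, -60.0, [], pv) == pytest.approx(20.0)

    def test_rhs_balance_and_pure_capacitor(self, space_small):
        pv = make_leak_only(space_small, g_leak=0.0, c_m=2.0)
        state = hh.ModelState.from_params(pv)
        d = hh.membrane_rhs(state, 10.0, pv)
        assert d.V == pytest.approx(5.0)  # I/C = 10 pA / 2 pF
        pv2 = make_leak_only(space_small, g_leak=1.0, e_leak=-70.0)
        state2 = hh.ModelState(V=-60.0, gates=state.gates)
        d2 = hh.membrane_rhs(state2, 10.0, pv2)  # leak current exactly balances
        assert d2.V == pytest.approx(0.0)

    def test_rhs_equals_per_channel_current_sum(self, registry, default_params):
        """Brute-force oracle: -(sum of 16 independent channel_current calls)/C
        + I/C equals the assembled right-hand side."""
        rng = np.random.default_rng(0)
        state = hh.ModelState(V=-40.0, gates=rng.uniform(0.1, 0.9, size=25))
        I_ext = 7.0
        d = hh.membrane_rhs(state, I_ext, default_params)
        total = 0.0
        i = 0
        for c in registry.channels:
            n = len(c.gates)
            total += hh.channel_current(c, state.V, state.gates[i : i + n], default_params)
            i += n
        expected = (-total + I_ext) / default_params["C_m"]
        assert d.V == pytest.approx(expected, rel=1e-12)

    def test_rhs_rejects_nonpositive_capacitance(self, space_small):
        pv = hh.assemble_parameter_vector(space_small)
        pv.values[pv.space.index("C_m")] = 0.0  # bypass bounds check deliberately
        state = hh.ModelState(V=-65.0, gates=np.full(25, 0.5))
        with pytest.raises(hh.ConfigError):
            hh.membrane_rhs(state, 0.0, pv)


class TestSteadyStateIV:
    def test_standard_protocol_has_18_points(self, default_params):
        iv = hh.steady_state_iv(default_params)
        assert iv.voltages.size == 18
        np.testing.assert_allclose(iv.voltages, np.arange(-120.0, 51.0, 10.0))

    def test_leak_only_iv_is_exactly_linear(self, space_small):
        pv = make_leak_only(space_small, g_leak=1.0, e_leak=-70.0)
        iv = hh.steady_state_iv(pv)
        assert iv.currents[0] == pytest.approx(-50.0)
        assert iv.currents[-1] == pytest.approx(120.0)
        slopes = np.diff(iv.currents) / np.diff(iv.voltages)
        np.testing.assert_allclose(slopes, 1.0, rtol=1e-13)

    def test_matches_long_voltage_clamp_simulation(self, space_small, vc_protocol):
        """Analytic gate fixation vs the terminal current of a 5 s clamp."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            pv = dg.sample_parameter_set(space_small, rng)
            analytic = hh.steady_state_iv(pv).currents
            simulated = pr.simulate_voltage_clamp(pv, vc_protocol, dt=0.1).currents
            scale = np.maximum(np.abs(analytic), 1.0)
            assert np.all(np.abs(simulated - analytic) / scale < 0.01)

    def test_rejects_nonincreasing_voltages(self):
        with pytest.raises(hh.ConfigError):
            hh.IVProfile(np.array([0.0, 0.0, 10.0]), np.zeros(3))
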