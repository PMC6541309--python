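"""Channel kinetics: printed curves, GHK, temperature scaling, updates."""
import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from tcneuron.channels import (
    CaDynamics,
    ChannelState,
    ConfigurationError,
    advance_gate,
    default_channels,
    eval_current,
    ghk_flux,
    ih_minf,
    ih_tau,
    load_channel,
    q10_scale,
    step_calcium,
)
from tcneuron.constants import FARADAY, GAS_CONSTANT, kelvin

VGRID = np.linspace(-120.0, 60.0, 361)


@pytest.fixture(scope="module")
def channels():
    return default_channels()


class TestIhKinetics:
    def test_half_activation_at_minus_86_4(self):
        assert ih_minf(-86.4) == pytest.approx(0.5, abs=1e-12)

    def test_boltzmann_value_one_slope_below_half(self):
        # v = -86.4 - 11.2 -> 1 / (1 + e^-1)
        assert ih_minf(-97.6) == pytest.approx(1 / (1 + np.exp(-1)), rel=1e-12)

    def test_saturation_and_monotonicity(self):
        v = np.linspace(-150, 100, 1001)
        m = ih_minf(v)
        assert np.all(np.diff(m) < 0)  # strictly decreasing
        assert ih_minf(100.0) < 1e-6
        assert ih_minf(-200.0) > 1 - 1e-4

    def test_tau_against_direct_formula(self):
        # independent evaluation of the printed sum-of-exponentials
        for v in (-110.0, -70.0, -40.0, 0.0):
            expected = 1.0 / (np.exp(-14.59 - 0.086 * v) + np.exp(-1.87 + 0.0701 * v))
            assert ih_tau(v) == pytest.approx(expected, rel=1e-12)
        assert ih_tau(-70.0) == pytest.approx(752.218, rel=1e-4)

    def test_tau_positive_with_single_interior_maximum(self):
        v = np.linspace(-120, 0, 2401)
        tau = ih_tau(v)
        assert np.all(tau > 0)
        peak = int(np.argmax(tau))
        assert 0 < peak < len(v) - 1
        # closed-form oracle: the denominator rate sum is minimized where
        # b1 e^{a1+b1 v} = -b2 e^{a2+b2 v}
        v_star = (np.log(0.0701 / 0.086) + 14.59 - 1.87) / (-0.086 - 0.0701)
        assert v[peak] == pytest.approx(v_star, abs=0.1)
        # ... which is close to (but not exactly) the rate-equality point
        v_eq = (-14.59 + 1.87) / (0.086 + 0.0701)
        assert abs(v_star - v_eq) < 2.0

    def test_channel_file_matches_printed_curves(self, channels):
        gate = channels["h"].gate("m")
        assert np.allclose(gate.steady_state(v=VGRID), ih_minf(VGRID))
        assert np.allclose(gate.time_constant(v=VGRID), ih_tau(VGRID), rtol=1e-9)


class TestGHK:
    def test_zero_at_symmetric_zero_voltage(self):
        assert ghk_flux(1e-4, 0.0, 2.0, 2.0) == 0.0

    def test_two_sided_continuity_at_zero(self):
        up = ghk_flux(1e-4, 1e-9, 5e-5, 2.0)
        dn = ghk_flux(1e-4, -1e-9, 5e-5, 2.0)
        limit = 1e-3 * 1e-4 * 2 * FARADAY * (5e-5 - 2.0)
        assert up == pytest.approx(limit, rel=1e-9)
        assert dn == pytest.approx(limit, rel=1e-9)

    def test_against_independent_constant_field_expression(self):
        # independent algebraic arrangement of the constant-field formula
        P, v, cai, cao, z, T = 1e-4, -80.0, 5e-5, 2.0, 2, kelvin(34.0)
        u = z * FARADAY * v * 1e-3 / (GAS_CONSTANT * T)
        expected = 1e-3 * P * z * FARADAY * u * (cai * np.exp(u) - cao) / (np.exp(u) - 1.0)
        got = ghk_flux(P, v, cai, cao, z=z, temp=34.0)
        assert got == pytest.approx(expected, rel=1e-10)
        assert got < 0  # physiological gradient at -80 mV -> inward

    def test_inward_at_rest_and_monotone_in_v(self):
        assert ghk_flux(1e-4, -60.0, 5e-5, 2.0) < 0
        v = np.linspace(-120, 60, 200)
        i = ghk_flux(1e-4, v, 5e-5, 2.0)
        assert np.all(np.diff(i) > 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ghk_flux(1e-4, -60.0, -1e-5, 2.0)


class TestQ10:
    def test_identity_at_reference(self):
        assert q10_scale(10.0, 34.0, 34.0, 2.8) == 10.0

    def test_definition_fold_change(self):
        assert q10_scale(10.0, 44.0, 34.0, 2.8) == pytest.approx(10.0 / 2.8)

    def test_half_decade_exponent(self):
        assert q10_scale(10.0, 39.0, 34.0, 3.0) == pytest.approx(10.0 / np.sqrt(3.0))

    @pytest.mark.parametrize("cid,q10", [("KA", 2.8), ("CaL", 3.0)])
    def test_channel_q10_values(self, channels, cid, q10):
        spec = channels[cid]
        assert spec.q10 == q10
        gate = spec.gates[0]
        tau_ref = gate.time_constant(v=-50.0, q10_factor=spec.q10_factor(spec.t_ref))
        tau_hot = gate.time_constant(
            v=-50.0, q10_factor=spec.q10_factor(spec.t_ref + 10.0))
        assert tau_ref / tau_hot == pytest.approx(q10, rel=1e-12)

    def test_temperature_scales_rates_not_steady_states(self, channels):
        for spec in channels.values():
            for gate in spec.gates:
                if gate.is_calcium_dependent:
                    continue
                ss = gate.steady_state(v=VGRID)
                assert np.array_equal(ss, gate.steady_state(v=VGRID))
                hot = gate.time_constant(v=VGRID, q10_factor=2.0)
                cold = gate.time_constant(v=VGRID, q10_factor=1.0)
                unfloored = cold / 2.0 > gate.tau_floor
                assert np.allclose(hot[unfloored], cold[unfloored] / 2.0)


class TestEvalCurrent:
    def test_zero_driving_force(self, channels):
        state = ChannelState({"m": 1.0, "h": 1.0})
        spec = channels["NaT"]
        assert eval_current(spec, 1.0, 50.0, state, e_na=50.0) == 0.0

    def test_closed_gate_blocks_current(self, channels):
        state = ChannelState({"m": 0.0, "h": 1.0})
        for v in (-80.0, 0.0, 40.0):
            assert eval_current(channels["NaT"], 1.0, v, state) == 0.0

    def test_ghk_channel_inward_at_rest(self, channels):
        state = ChannelState({"m": 0.5, "h": 0.5}, cai=5e-5)
        assert eval_current(channels["CaT"], 1e-4, -60.0, state) < 0

    def test_ka_two_component_weighted_sum(self, channels):
        spec = channels["KA"]
        state = ChannelState({"m1": 0.5, "h1": 0.5, "m2": 0.25, "h2": 1.0})
        po = 0.6 * 0.5**4 * 0.5 + 0.4 * 0.25**4 * 1.0
        got = eval_current(spec, 0.01, -30.0, state, e_k=-90.0)
        assert got == pytest.approx(0.01 * po * (-30.0 + 90.0), rel=1e-12)

    def test_unknown_gate_is_configuration_error(self, channels):
        with pytest.raises(ConfigurationError):
            eval_current(channels["NaT"], 1.0, -60.0, ChannelState({"m": 1.0}))


class TestGateProperties:
    def test_all_steady_states_bounded(self, channels):
        cai_grid = np.logspace(-6, -1, 60)
        for spec in channels.values():
            for gate in spec.gates:
                if gate.is_calcium_dependent:
                    ss = gate.steady_state(cai=cai_grid)
                else:
                    ss = gate.steady_state(v=VGRID)
                assert np.all((ss >= 0.0) & (ss <= 1.0)), (spec.id, gate.name)

    def test_all_taus_positive_after_flooring(self, channels):
        for spec in channels.values():
            qf = spec.q10_factor(34.0)
            for gate in spec.gates:
                if gate.is_calcium_dependent:
                    continue
                tau = gate.time_constant(v=VGRID, q10_factor=qf)
                assert np.all(tau > 0), (spec.id, gate.name)

    def test_sk_voltage_independent_and_monotone_in_calcium(self, channels):
        gate = channels["SK"].gate("z")
        assert gate.is_calcium_dependent
        cai = np.logspace(-6, -1, 100)
        act = gate.steady_state(cai=cai)
        assert np.all(np.diff(act) > 0)
        assert gate.steady_state(cai=0.00043) == pytest.approx(0.5, rel=1e-9)


class TestAdvanceGate:
    def test_fixed_point(self, channels):
        gate = channels["CaT"].gate("m")
        ninf = float(gate.steady_state(v=-60.0))
        assert advance_gate(gate, ninf, -60.0, dt=0.1) == pytest.approx(ninf, abs=1e-12)

    def test_relaxation_limit(self, channels):
        gate = channels["CaT"].gate("m")
        ninf = float(gate.steady_state(v=-60.0))
        tau = float(gate.time_constant(v=-60.0))
        out = advance_gate(gate, 0.0, -60.0, dt=50.0 * tau)
        assert out == pytest.approx(ninf, abs=1e-6)

    def test_matches_adaptive_ode_oracle_at_fixed_voltage(self, channels):
        gate = channels["h"].gate("m")
        v, n0, t_end = -75.0, 0.1, 40.0
        ninf = float(gate.steady_state(v=v))
        tau = float(gate.time_constant(v=v))
        sol = solve_ivp(lambda t, n: (ninf - n) / tau, (0.0, t_end), [n0],
                        rtol=1e-10, atol=1e-12)
        stepped = n0
        n_steps = 400
        for _ in range(n_steps):
            stepped = float(advance_gate(gate, stepped, v, dt=t_end / n_steps))
        assert stepped == pytest.approx(sol.y[0, -1], abs=1e-8)


class TestCalciumDynamics:
    def test_equilibrium(self):
        dyn = CaDynamics()
        assert step_calcium(dyn, dyn.ca_baseline, 0.0, 1.0) == pytest.approx(
            dyn.ca_baseline)

    def test_decay_matches_closed_form(self):
        dyn = CaDynamics(tau_decay=120.0)
        c0, dt = 1e-3, 7.0
        expected = dyn.ca_baseline + (c0 - dyn.ca_baseline) * np.exp(-dt / 120.0)
        assert step_calcium(dyn, c0, 0.0, dt) == pytest.approx(expected, rel=1e-12)

    def test_doubling_tau_halves_decay_rate(self):
        c0 = 1e-3
        d1 = CaDynamics(tau_decay=100.0)
        d2 = CaDynamics(tau_decay=200.0)
        r1 = -(step_calcium(d1, c0, 0.0, 1e-3) - c0) / 1e-3
        r2 = -(step_calcium(d2, c0, 0.0, 1e-3) - c0) / 1e-3
        assert r1 / r2 == pytest.approx(2.0, rel=1e-3)

    def test_outward_current_cannot_deplete_below_baseline(self):
        dyn = CaDynamics()
        c = dyn.ca_baseline
        for _ in range(100):
            c = step_calcium(dyn, c, +0.5, 1.0)  # outward
        assert c >= dyn.ca_baseline - 1e-15

    def test_inward_current_raises_concentration(self):
        dyn = CaDynamics()
        c = step_calcium(dyn, dyn.ca_baseline, -0.1, 1.0)
        assert c > dyn.ca_baseline


def test_channel_files_are_editable(tmp_path, channels):
    """The engine is data-driven: a modified constant takes effect."""
    import yaml
    from importlib import resources
    from tcneuron.channels import load_channel_file

    text = (resources.files("tcneuron.channels") / "data" / "h.yaml").read_text()
    doc = yaml.safe_load(text)
    doc["gates"][0]["params"]["inf"]["vhalf"] = -80.0
    p = tmp_path / "h_mod.yaml"
    p.write_text(yaml.safe_dump(doc))
    spec = load_channel_file(p)
    assert spec.gate("m").steady_state(v=-80.0) == pytest.approx(0.5)
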