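"""Cell building and cable integration: geometry, passive physics,
solver correctness against an independent adaptive-ODE oracle."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tcneuron.cell import (
    Morphology,
    Section,
    SimConfig,
    ValidationError,
    build_cell,
    default_parameter_vector,
    discretize,
    read_swc,
    replace_axon_with_stub,
    simulate,
    single_compartment_reduction,
    steady_state_voltage,
    write_swc,
)
from tcneuron.cell.model import RegionDistribution
from tcneuron.cell.simulate import Trace
from tcneuron.channels import default_channels
from tcneuron.constants import FARADAY, GAS_CONSTANT, kelvin
from tcneuron.stimuli import Protocol
from tcneuron.synthetic_data import make_morphology

from conftest import leak_only_cell, sphere_morphology


def straight_dendrite_morphology(L=100.0, diam=2.0, n_pts=11):
    soma = Section("soma", np.zeros((1, 3)), np.array([20.0]))
    z = np.linspace(10.0, 10.0 + L, n_pts)
    pts = np.column_stack([np.zeros(n_pts), np.zeros(n_pts), z])
    dend = Section("dend", pts, np.full(n_pts, diam), parent=0)
    return Morphology([soma, dend])


class TestMorphologyIO:
    def test_swc_round_trip_preserves_geometry(self, tmp_path):
        m = make_morphology(5)
        p = tmp_path / "m.swc"
        write_swc(m, p)
        m2 = read_swc(p)
        assert len(m2.sections_of("dend")) == len(m.sections_of("dend"))
        assert m2.total_length("dend") == pytest.approx(m.total_length("dend"), rel=1e-3)
        g1 = discretize(m)
        g2 = discretize(m2)
        assert g2.total_area == pytest.approx(g1.total_area, rel=1e-3)

    def test_single_soma_invariant(self):
        with pytest.raises(ValueError):
            Morphology([Section("dend", np.zeros((1, 3)), np.array([1.0]))])


class TestAxonStub:
    def test_long_axon_replaced(self):
        m = make_morphology(2)
        assert m.sections_of("axon")
        stubbed = replace_axon_with_stub(m)
        axons = [stubbed.sections[i] for i in stubbed.sections_of("axon")]
        assert len(axons) == 2
        assert all(a.length == pytest.approx(30.0) for a in axons)
        assert all(np.allclose(a.diams, 1.0) for a in axons)

    def test_missing_axon_gets_stub(self):
        m = straight_dendrite_morphology()
        stubbed = replace_axon_with_stub(m)
        assert len(stubbed.sections_of("axon")) == 2

    def test_dendrites_untouched(self):
        m = make_morphology(2)
        stubbed = replace_axon_with_stub(m)
        assert stubbed.total_length("dend") == pytest.approx(m.total_length("dend"))


class TestDiscretize:
    @pytest.mark.parametrize("L,nseg", [(100.0, 3), (40.0, 1), (41.0, 2), (120.0, 3)])
    def test_segment_count_is_ceil(self, L, nseg):
        m = straight_dendrite_morphology(L=L)
        g = discretize(m, seg_len=40.0)
        assert len(g.comps_of_section[1]) == nseg

    def test_total_area_conserved_across_seg_lengths(self):
        m = make_morphology(3)
        a40 = discretize(m, seg_len=40.0).total_area
        a10 = discretize(m, seg_len=10.0).total_area
        a7 = discretize(m, seg_len=7.0).total_area
        assert a10 == pytest.approx(a40, rel=1e-9)
        assert a7 == pytest.approx(a40, rel=1e-9)

    def test_parent_precedes_child(self):
        g = discretize(make_morphology(3))
        assert g.parent[0] == -1
        assert np.all(g.parent[1:] < np.arange(1, g.n))


class TestBuildCell:
    def test_cat_density_shared_soma_dendrites(self, gt_cnad):
        cell = gt_cnad.build()
        dm = cell.density_map()
        assert dm[("soma", "CaT")] == dm[("dend", "CaT")]

    def test_out_of_bounds_parameter_lists_offender(self):
        pv = default_parameter_vector({"gNaT.s": 5.0})
        with pytest.raises(ValidationError, match="gNaT.s"):
            build_cell(sphere_morphology(), params=pv)

    def test_unknown_region_rejected(self):
        with pytest.raises(ValidationError):
            RegionDistribution({"soma": [("leak", "gleak.s")],
                                "nucleus": []})

    def test_default_configuration_has_22_parameters(self):
        assert len(default_parameter_vector()) == 22


class TestPassivePhysics:
    def test_leak_only_rests_at_minus_79(self):
        cell = leak_only_cell()
        assert steady_state_voltage(cell, 0.0) == pytest.approx(-79.0, abs=1e-3)

    def test_rc_step_response_closed_form(self):
        cell = leak_only_cell(gleak=1e-4)
        A = cell.graph.total_area
        gA = 1e-4 * A * 1e6  # uS
        amp = 0.1
        proto = Protocol("step", 0.0, [{"kind": "step", "amp": amp,
                                        "t0": 500.0, "t1": 2500.0}], 2500.0,
                         onset_delay=0.0)
        tr = simulate(cell, proto)
        dv = tr.v[-1] + 79.0
        assert dv == pytest.approx(amp / gA, rel=5e-3)
        # membrane time constant from the 1 - 1/e point
        tau_expected = (1.0 * A * 1e3) / gA  # nF / uS = ms
        target = -79.0 + (1 - np.exp(-1)) * amp / gA
        after = tr.t >= 500.0
        tau_sim = tr.t[after][np.argmax(tr.v[after] >= target)] - 500.0
        assert tau_sim == pytest.approx(tau_expected, rel=5e-3)

    def test_initialization_drift_below_1mv(self):
        cell = leak_only_cell()
        proto = Protocol("rest", 0.0, [], 1000.0, onset_delay=0.0)
        tr = simulate(cell, proto)
        assert np.max(np.abs(tr.v - tr.v[0])) < 1.0

    def test_active_model_initialized_at_rest_stays_put(self, gt_cnad):
        from dataclasses import replace

        cell = gt_cnad.build(reduced=True)
        rest = steady_state_voltage(cell, 0.0, duration=3000.0)
        cfg = replace(cell.config, v_init=rest)
        cell2 = cell.with_params(cell.params)
        cell2.config = cfg
        tr = simulate(cell2, Protocol("rest", 0.0, [], 1000.0, onset_delay=0.0))
        assert np.max(np.abs(tr.v - rest)) < 1.0


def _toy_cell():
    """Soma + 2-compartment dendrite with leak, h and CaT (subthreshold)."""
    m = straight_dendrite_morphology(L=80.0, diam=2.0)
    dist = RegionDistribution({
        "soma": [("leak", "gleak.s"), ("h", "gh.s"), ("CaT", "pCaT.sd")],
        "dend": [("leak", "gleak.s"), ("h", "gh.s"), ("CaT", "pCaT.sd")],
        "axon": [("leak", "gleak.s")],
    })
    from tcneuron.cell.model import ParameterVector

    pv = ParameterVector(
        ["gleak.s", "gh.s", "pCaT.sd", "gamma_Ca", "tau_Ca"],
        np.array([5e-5, 3e-6, 5e-5, 0.005, 100.0]),
        np.array([1e-7, 1e-9, 1e-9, 0.001, 20.0]),
        np.array([1.0, 1.0, 1.0, 0.05, 300.0]))
    return build_cell(m, dist=dist, params=pv, expected_count=None,
                      add_axon_stub=False)


def _reference_rhs(cell, istim_fn):
    """Independent RHS builder from the declarative channel specs."""
    g = cell.graph
    cfg = cell.config
    chans = cell.channels
    dens = cell.density_map()
    region_names = {0: "soma", 1: "dend", 2: "axon"}
    gates = []  # (cid, gate, rows slice index)
    used = []
    for region in ("soma", "dend", "axon"):
        for cid, _ in cell.distribution.regions.get(region, []):
            if cid not in used:
                used.append(cid)
    for cid in used:
        for gate in chans[cid].gates:
            gates.append((cid, gate))
    nc, ng = g.n, len(gates)
    cap = cfg.cm * g.area * 1e3  # nF
    area6 = g.area * 1e6
    T = kelvin(cfg.temperature)

    def density(i, cid):
        return dens.get((region_names[int(g.region[i])], cid), 0.0)

    def rhs(t, y):
        v = y[:nc]
        G = y[nc:nc + ng * nc].reshape(ng, nc)
        cai = y[nc + ng * nc:]
        dv = np.zeros(nc)
        dG = np.zeros((ng, nc))
        dca = np.zeros(nc)
        state_by_chan = {}
        for r, (cid, gate) in enumerate(gates):
            state_by_chan.setdefault(cid, {})[gate.name] = G[r]
            qf = chans[cid].q10_factor(cfg.temperature)
            if gate.is_calcium_dependent:
                ninf = gate.steady_state(cai=cai)
                tau = gate.time_constant(v=v, q10_factor=qf)
            else:
                ninf = gate.steady_state(v=v)
                tau = gate.time_constant(v=v, q10_factor=qf)
            dG[r] = (ninf - G[r]) / tau
        for i in range(nc):
            itot = 0.0
            ica = 0.0
            for cid in used:
                d = density(i, cid)
                if d == 0.0:
                    continue
                spec = chans[cid]
                po = 0.0
                for term in spec.terms:
                    prod = term["weight"]
                    for gname, expo in term["gates"].items():
                        r = next(k for k, (c2, g2) in enumerate(gates)
                                 if c2 == cid and g2.name == gname)
                        prod *= G[r, i] ** expo
                    po += prod
                if spec.is_ghk:
                    z = spec.conduction.get("z", 2)
                    cao = spec.conduction.get("cao", 2.0)
                    u = z * FARADAY * v[i] * 1e-3 / (GAS_CONSTANT * T)
                    if abs(u) < 1e-9:
                        flux = 1e-3 * z * FARADAY * (cai[i] - cao)
                    else:
                        flux = (1e-3 * z * FARADAY * u
                                * (cai[i] - cao * np.exp(-u)) / (1 - np.exp(-u)))
                    idens = d * po * flux
                    ica += idens
                else:
                    erev = spec.resolve_erev(cfg.e_na, cfg.e_k)
                    idens = d * po * (v[i] - erev)
                itot += idens * area6[i]
            dv[i] = -itot
            src = max(-1e4 * cell.ca_dynamics.gamma * ica
                      / (2 * FARADAY * cell.ca_dynamics.shell_depth), 0.0)
            dca[i] = src - (cai[i] - cell.ca_dynamics.ca_baseline) \
                / cell.ca_dynamics.tau_decay
        for i in range(1, nc):
            p = g.parent[i]
            ia = g.gax[i] * (v[i] - v[p])
            dv[i] -= ia
            dv[p] += ia
        dv[0] += istim_fn(t)
        return np.concatenate([dv / cap, dG.ravel(), dca])

    return rhs, nc, ng


class TestSolverOracle:
    def test_matches_adaptive_ode_on_toy_cell(self):
        cell = _toy_cell()
        amp, t0s, t_end = -0.05, 20.0, 220.0
        proto = Protocol("step", 0.0, [{"kind": "step", "amp": amp,
                                        "t0": t0s, "t1": t_end}], t_end,
                         onset_delay=0.0)
        tr = simulate(cell, proto)
        rhs, nc, ng = _reference_rhs(cell, lambda t: amp if t >= t0s else 0.0)
        cfg = cell.config
        y0 = np.full(nc, cfg.v_init)
        G0 = []
        used = []
        for region in ("soma", "dend", "axon"):
            for cid, _ in cell.distribution.regions.get(region, []):
                if cid not in used:
                    used.append(cid)
        for cid in used:
            for gate in cell.channels[cid].gates:
                if gate.is_calcium_dependent:
                    G0.append(np.full(nc, float(gate.steady_state(
                        cai=cell.ca_dynamics.ca_baseline))))
                else:
                    G0.append(np.full(nc, float(gate.steady_state(v=cfg.v_init))))
        y0 = np.concatenate([y0, np.ravel(G0),
                             np.full(nc, cell.ca_dynamics.ca_baseline)])
        sol = solve_ivp(rhs, (0.0, t_end), y0, t_eval=tr.t, rtol=1e-9,
                        atol=1e-11, method="LSODA",
                        max_step=1.0)
        err = np.max(np.abs(sol.y[0] - tr.v))
        assert err < 0.05

    def test_section_order_permutation_invariance(self):
        soma = Section("soma", np.zeros((1, 3)), np.array([20.0]))

        def dend(direction):
            z = np.linspace(10, 110, 11)
            pts = np.column_stack([direction * z, np.zeros(11), np.zeros(11)])
            return Section("dend", pts, np.full(11, 2.0), parent=0)

        mAB = Morphology([soma, dend(+1.0), dend(-1.0)])
        mBA = Morphology([soma, dend(-1.0), dend(+1.0)])
        pv = default_parameter_vector({"gleak.s": 5e-5, "gleak.d": 5e-5,
                                       "gleak.a": 5e-5, "gNaT.s": 0.1,
                                       "gKd.s": 0.05})
        proto = Protocol("step", 0.0, [{"kind": "step", "amp": 0.08,
                                        "t0": 100.0, "t1": 400.0}], 500.0,
                         onset_delay=0.0)
        trA = simulate(build_cell(mAB, params=pv), proto)
        trB = simulate(build_cell(mBA, params=pv), proto)
        assert np.max(np.abs(trA.v - trB.v)) < 1e-6

    def test_dt_halving_convergence_on_burst(self, cnad_cell, cnad_norm):
        from tcneuron.efeatures import detect_spikes

        ih_t, ih_b, thr = cnad_norm
        proto = Protocol("burst", ih_b, [{"kind": "step", "amp": 1.25 * thr,
                                          "t0": 800.0, "t1": 2150.0}], 2400.0)
        tr1 = simulate(cnad_cell, proto, dt=0.025)
        tr2 = simulate(cnad_cell, proto, dt=0.0125)
        s1 = detect_spikes(tr1).times
        s2 = detect_spikes(tr2).times
        assert len(s1) == len(s2)
        assert np.max(np.abs(s1 - s2)) < 0.5  # spike times stable [ms]
        # subthreshold part of the trace converges pointwise
        sub = np.ones(len(tr1.t), dtype=bool)
        for s in s1:
            sub &= ~((tr1.t > s - 3.0) & (tr1.t < s + 6.0))
        v2 = np.interp(tr1.t, tr2.t, tr2.v)
        assert np.max(np.abs(tr1.v[sub] - v2[sub])) < 0.5


class TestReduction:
    def test_area_preserved(self, gt_cnad):
        full = gt_cnad.build()
        red = single_compartment_reduction(full)
        assert red.graph.total_area == pytest.approx(full.graph.total_area,
                                                     rel=1e-9)

    def test_passive_input_resistance_close_to_full_model(self, gt_cnad):
        # passive variant: only leak retained
        full = gt_cnad.build()
        passive_vals = {n: (v if n.startswith("gleak") or n in ("gamma_Ca", "tau_Ca")
                            else full.params.lower[i])
                        for i, (n, v) in enumerate(zip(full.params.names,
                                                       full.params.values))}
        pv = full.params.with_values(
            np.array([passive_vals[n] for n in full.params.names]))
        full_p = full.with_params(pv)
        red_p = single_compartment_reduction(full_p)

        def rin(cell):
            v0 = steady_state_voltage(cell, 0.0)
            v1 = steady_state_voltage(cell, -0.02)
            return (v1 - v0) / (-0.02)

        assert rin(red_p) == pytest.approx(rin(full_p), rel=0.02)


class TestTrace:
    def test_table_round_trip_exact(self, tmp_path):
        cell = leak_only_cell()
        tr = simulate(cell, Protocol("r", 0.01, [], 100.0, onset_delay=0.0))
        p = tmp_path / "trace.txt"
        tr.to_table(p)
        tr2 = Trace.from_table(p)
        assert np.array_equal(tr.v, tr2.v)
        assert np.array_equal(tr.t, tr2.t)

    def test_npz_round_trip_exact(self, tmp_path):
        cell = leak_only_cell()
        tr = simulate(cell, Protocol("r", 0.01, [], 100.0, onset_delay=0.0))
        p = tmp_path / "trace.npz"
        tr.to_npz(p)
        tr2 = Trace.from_npz(p)
        assert np.array_equal(tr.v, tr2.v)

    def test_divergence_reported(self):
        cell = leak_only_cell(gleak=1e-6, diam_um=5.0)
        from tcneuron.cell.simulate import SimulationError

        with pytest.raises(SimulationError, match="diverged"):
            simulate(cell, Protocol("kill", 5.0, [], 200.0, onset_delay=0.0))
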