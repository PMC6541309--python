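"""Feature extraction, e-type classification, objective errors, ranking."""
import numpy as np
import pytest
from scipy.signal import find_peaks

from tcneuron.cell import simulate
from tcneuron.cell.simulate import Trace
from tcneuron.efeatures import (
    AI_CUTOFF,
    PENALTY_ERROR,
    FeatureTarget,
    SpikeTrain,
    TargetSet,
    adaptation_index,
    classify_etype,
    detect_spikes,
    extract_features,
    input_resistance,
    objective_errors,
    rank_models,
)
from tcneuron.stimuli import Protocol

from conftest import leak_only_cell


def _train(times):
    t = np.asarray(times, dtype=float)
    z = np.zeros_like(t)
    return SpikeTrain(t, z, z, z, z)


def synthetic_trace(spike_times, duration=1000.0, dt=0.1, base=-70.0):
    """Triangular spikes riding on a flat baseline."""
    t = np.arange(0.0, duration, dt)
    v = np.full_like(t, base)
    for ts in spike_times:
        rise = (t >= ts) & (t < ts + 1.0)
        fall = (t >= ts + 1.0) & (t < ts + 2.0)
        v[rise] += (t[rise] - ts) * 100.0  # 100 mV/ms upstroke
        v[fall] += (2.0 - (t[fall] - ts)) * 100.0
    return Trace(t, v, np.zeros_like(t))


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 1000.0, 0.1)
        tr = Trace(t, np.full_like(t, -79.0), np.zeros_like(t))
        assert len(detect_spikes(tr)) == 0

    def test_single_triangle_spike(self):
        tr = synthetic_trace([500.0])
        st = detect_spikes(tr)
        assert len(st) == 1
        assert st.peaks[0] == pytest.approx(30.0, abs=1.0)

    def test_count_matches_independent_peak_finder(self, cnad_cell, cnad_battery):
        proto = cnad_battery["Step_200"]
        tr = simulate(cnad_cell, proto)
        st = detect_spikes(tr)
        peaks, _ = find_peaks(tr.v, height=-20.0, distance=int(1.0 / tr.dt))
        assert len(st) == len(peaks)

    def test_slow_crossing_is_not_a_spike(self):
        # passive charging through -20 mV at ~1 mV/ms
        t = np.arange(0, 200.0, 0.1)
        v = -79.0 + 90.0 * (1 - np.exp(-t / 60.0))
        tr = Trace(t, v, np.zeros_like(t))
        assert len(detect_spikes(tr)) == 0


class TestAdaptationIndex:
    def test_constant_isis_give_zero(self):
        assert adaptation_index(_train([0, 50, 100, 150])) == pytest.approx(0.0)

    def test_printed_arithmetic_example(self):
        # ISIs 100 and 110 ms -> (110-100)/(110+100)
        ai = adaptation_index(_train([0.0, 100.0, 210.0]))
        assert ai == pytest.approx(10.0 / 210.0)

    def test_lengthening_isis_positive(self):
        ai = adaptation_index(_train([0, 50, 110, 180, 260]))
        assert ai > 0

    def test_undefined_below_three_spikes(self):
        assert adaptation_index(_train([0, 50])) is None


class TestClassifyEtype:
    def test_boundary_value_is_adapting(self):
        labels, cutoff = classify_etype([AI_CUTOFF])
        assert labels[0] == "cAD_ltb"
        assert cutoff == AI_CUTOFF

    def test_all_zero_values_non_adapting(self):
        labels, _ = classify_etype(np.zeros(5))
        assert all(l == "cNAD_ltb" for l in labels)

    def test_refit_recovers_equal_posterior_cutoff(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.01, 0.005, 120)
        b = rng.normal(0.06, 0.010, 80)
        values = np.concatenate([a, b])
        labels, cutoff = classify_etype(values)
        # oracle: equal-posterior point of the generating mixture on a grid
        from scipy.stats import norm

        grid = np.linspace(0.01, 0.06, 20001)
        post = (0.6 * norm.pdf(grid, 0.01, 0.005)
                - 0.4 * norm.pdf(grid, 0.06, 0.010))
        oracle = grid[np.argmin(np.abs(post))]
        assert cutoff == pytest.approx(oracle, abs=0.005)
        assert np.mean(labels[:120] == "cNAD_ltb") > 0.9
        assert np.mean(labels[120:] == "cAD_ltb") > 0.9

    def test_degenerate_mixture_falls_back_with_warning(self):
        vals = np.full(50, 0.02)  # no bimodality at all
        with pytest.warns(UserWarning, match="degenerate"):
            _, cutoff = classify_etype(vals)
        assert cutoff == AI_CUTOFF


class TestExtractFeatures:
    def test_passive_hyperpolarizing_step_has_zero_sag(self):
        cell = leak_only_cell()
        proto = Protocol("iv", 0.0, [{"kind": "step", "amp": -0.05,
                                      "t0": 800.0, "t1": 3800.0}], 4000.0)
        tr = simulate(cell, proto)
        feats = extract_features(tr, proto, ["sag_amplitude", "voltage_base"])
        assert feats["sag_amplitude"] == pytest.approx(0.0, abs=0.05)
        assert feats["voltage_base"] == pytest.approx(-79.0, abs=0.1)

    def test_input_resistance_closed_form(self):
        cell = leak_only_cell(gleak=1e-4)
        gA = 1e-4 * cell.graph.total_area * 1e6
        points = []
        for amp in (-0.06, -0.03, 0.0):
            proto = Protocol("iv", 0.0, [{"kind": "step", "amp": amp,
                                          "t0": 800.0, "t1": 3800.0}], 4000.0)
            tr = simulate(cell, proto)
            feats = extract_features(tr, proto, ["steady_state_voltage"])
            points.append((amp, feats["steady_state_voltage"]))
        assert input_resistance(points) == pytest.approx(1.0 / gA, rel=0.01)

    def test_unstimulated_leak_trace_voltage_base(self):
        cell = leak_only_cell()
        proto = Protocol("spon", 0.0, [], 2000.0, onset_delay=0.0)
        tr = simulate(cell, proto)
        feats = extract_features(tr, proto, ["voltage_base"])
        assert feats["voltage_base"] == pytest.approx(-79.0, abs=0.05)

    def test_undefined_features_flagged_not_zero(self):
        cell = leak_only_cell()
        proto = Protocol("spon", 0.0, [], 1000.0, onset_delay=0.0)
        tr = simulate(cell, proto)
        feats = extract_features(tr, proto, ["adaptation_index", "inv_first_ISI",
                                             "time_to_first_spike"])
        assert all(v is None for v in feats.values())

    def test_unknown_feature_rejected(self):
        cell = leak_only_cell()
        proto = Protocol("spon", 0.0, [], 200.0, onset_delay=0.0)
        tr = simulate(cell, proto)
        with pytest.raises(ValueError, match="unknown"):
            extract_features(tr, proto, ["resting_sodium"])

    def test_extraction_is_reproducible(self, cnad_cell, cnad_battery):
        proto = cnad_battery["Step_150"]
        tr = simulate(cnad_cell, proto)
        names = ["spike_count", "AP_amplitude", "AP_half_width", "AHP_depth"]
        a = extract_features(tr, proto, names)
        b = extract_features(tr, proto, names)
        assert a == b


class TestObjectiveErrors:
    def _targets(self):
        return TargetSet([
            FeatureTarget("spike_count", "Step_200", "tonic", 20.0, 4.0),
            FeatureTarget("AP_amplitude", "Step_200", "tonic", 70.0, 5.0),
        ], 0.2, 0.05, -0.02)

    def test_exact_match_is_zero(self):
        errs = objective_errors({("Step_200", "spike_count"): 20.0,
                                 ("Step_200", "AP_amplitude"): 70.0},
                                self._targets())
        assert all(e == 0.0 for e in errs.values())

    def test_three_std_boundary(self):
        errs = objective_errors({("Step_200", "spike_count"): 32.0,
                                 ("Step_200", "AP_amplitude"): 70.0},
                                self._targets())
        assert errs[("Step_200", "spike_count")] == pytest.approx(3.0)

    def test_missing_feature_gets_penalty(self):
        errs = objective_errors({("Step_200", "spike_count"): None,
                                 ("Step_200", "AP_amplitude"): 70.0},
                                self._targets())
        assert errs[("Step_200", "spike_count")] == PENALTY_ERROR

    def test_zero_std_rejected(self):
        with pytest.raises(ValueError, match="STD"):
            FeatureTarget("spike_count", "Step_200", "tonic", 20.0, 0.0)


class TestRankModels:
    def test_smaller_max_wins(self):
        order = rank_models([{"a": 2.1}, {"a": 2.9}])
        assert order == [0, 1]

    def test_tie_broken_by_sum(self):
        e1 = {"a": 3.0, "b": 3.0, "c": 4.0}   # max 4, sum 10
        e2 = {"a": 4.0, "b": 4.0, "c": 4.0}   # max 4, sum 12
        assert rank_models([e2, e1]) == [1, 0]

    def test_invariant_to_feature_permutation(self):
        e = {"a": 1.0, "b": 2.0, "c": 0.5}
        ep = {"c": 0.5, "a": 1.0, "b": 2.0}
        assert rank_models([e, {"a": 5.0}]) == rank_models([ep, {"a": 5.0}])

    def test_stable_for_full_ties(self):
        assert rank_models([{"a": 1.0}, {"a": 1.0}]) == [0, 1]


def test_target_set_csv_round_trip(tmp_path, cnad_population):
    ts = cnad_population.target_set
    p = tmp_path / "targets.csv"
    ts.to_csv(p)
    ts2 = TargetSet.from_csv(p)
    assert ts2.i_thr == ts.i_thr
    assert len(ts2) == len(ts)
    for a, b in zip(ts, ts2):
        assert a.feature == b.feature and a.mean == pytest.approx(b.mean)
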