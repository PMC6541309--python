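"""Virtual cell populations and feature-target generation.

A population emulates a set of recorded cells of one e-type: the
ground-truth parameters are jittered log-normally per cell, every
virtual cell is re-normalized exactly like an experimental one
(holding-current search for both modes, rheobase search, battery
scaled to its own rheobase), features are extracted from the simulated
battery, and the per-feature mean/STD table is assembled in the same
layout as an experimental feature spreadsheet.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..cell.model import CellModel, ParameterVector
from ..cell.simulate import SimulationError, Trace, simulate
from ..efeatures import FeatureTarget, TargetSet, extract_features
from ..stimuli import (
    ECodeBattery,
    SearchError,
    V_BURST,
    V_TONIC,
    find_holding,
    find_rheobase,
    make_battery,
)
from .ground_truth import GroundTruthModel

__all__ = ["VirtualPopulation", "make_population", "DEFAULT_OBJECTIVES",
           "FAST_OBJECTIVES", "evaluate_objectives"]

log = logging.getLogger(__name__)

# (protocol, feature) pairs used as optimization objectives: passive
# properties, tonic and burst firing, spike shape, and the zero-spike
# guards at rest and on holding.
DEFAULT_OBJECTIVES: List[Tuple[str, str]] = [
    *[(f"Step_{p}", f) for p in (150, 200, 250)
      for f in ("spike_count", "adaptation_index", "inv_first_ISI",
                "inv_last_ISI", "time_to_first_spike", "AP_amplitude",
                "AP_half_width", "AHP_depth", "voltage_base")],
    ("StepBurst_125", "spike_count"),
    ("StepBurst_125", "inv_first_ISI"),
    ("StepBurst_125", "time_to_first_spike"),
    ("StepBurst_125", "voltage_base"),
    ("IV_-140", "sag_amplitude"),
    ("IV_-140", "steady_state_voltage"),
    ("IV_-140", "voltage_base"),
    ("IV_-40", "steady_state_voltage"),
    ("SponNoHold", "spike_count"),
    ("SponNoHold", "voltage_base"),
    ("SponHold", "spike_count"),
]

# Reduced objective set for scaled-down runs (fewer, shorter protocols).
FAST_OBJECTIVES: List[Tuple[str, str]] = [
    ("Step_200", "spike_count"),
    ("Step_200", "adaptation_index"),
    ("Step_200", "inv_first_ISI"),
    ("Step_200", "AP_amplitude"),
    ("Step_200", "voltage_base"),
    ("StepBurst_125", "spike_count"),
    ("StepBurst_125", "inv_first_ISI"),
    ("IV_-140", "sag_amplitude"),
    ("IV_-140", "steady_state_voltage"),
    ("SponHold", "spike_count"),
]

# STD floors keep targets meaningful when jitter is small; they play
# the role of measurement noise on the target side.
_STD_FLOORS = {
    "spike_count": 0.5,
    "voltage_base": 0.25,
    "steady_state_voltage": 0.25,
    "sag_amplitude": 0.25,
    "AP_amplitude": 0.5,
    "AHP_depth": 0.5,
    "AP_half_width": 0.05,
    "time_to_first_spike": 2.0,
    "inv_first_ISI": 1.0,
    "inv_last_ISI": 1.0,
    "adaptation_index": 0.005,
    "mean_frequency": 0.5,
    "ISI_mean": 1.0,
}


def _std_floor(feature: str, mean: float) -> float:
    # absolute floors for tabulated features (voltages are offsets, so a
    # relative floor would be meaningless for them)
    if feature in _STD_FLOORS:
        return _STD_FLOORS[feature]
    return max(0.05 * abs(mean), 1e-3)


def evaluate_objectives(cell: CellModel, battery: ECodeBattery,
                        objectives: Sequence[Tuple[str, str]],
                        noise_sd: float = 0.0,
                        rng: Optional[np.random.Generator] = None,
                        ) -> Dict[Tuple[str, str], Optional[float]]:
    """Simulate each protocol an objective references and extract features.

    Optional additive Gaussian voltage noise (SD in mV) emulates
    measurement noise before extraction.
    """
    by_proto: Dict[str, List[str]] = {}
    for proto, feat in objectives:
        by_proto.setdefault(proto, []).append(feat)
    out: Dict[Tuple[str, str], Optional[float]] = {}
    for proto_name, feats in by_proto.items():
        proto = battery[proto_name]
        trace = simulate(cell, proto)
        if noise_sd > 0:
            noisy = Trace(trace.t,
                          trace.v + (rng or np.random.default_rng()).normal(
                              0.0, noise_sd, size=len(trace.v)),
                          trace.i, trace.meta)
        else:
            noisy = trace
        vals = extract_features(noisy, proto, feats)
        for f in feats:
            out[(proto_name, f)] = vals[f]
    return out


@dataclass
class VirtualPopulation:
    """Jittered cells, their normalization currents and features."""

    etype: str
    cells: List[ParameterVector]
    currents: pd.DataFrame  # per cell: i_thr, i_hold_tonic, i_hold_burst
    features: pd.DataFrame  # per cell x (protocol, feature) value
    target_set: TargetSet = field(repr=False, default=None)


def make_population(gt: GroundTruthModel, n: int = 10, jitter: float = 0.15,
                    seed: int = 0,
                    objectives: Sequence[Tuple[str, str]] = None,
                    noise_sd: float = 0.2,
                    reduced: bool = True,
                    max_resample: int = 4) -> VirtualPopulation:
    """Generate a virtual population and its feature-target table.

    ``jitter`` is the SD of the multiplicative log-normal perturbation
    applied independently to every free parameter; cells whose holding
    or rheobase search fails are resampled (logged).  ``reduced``
    runs each virtual cell as its single-compartment surrogate.
    """
    if n < 10:
        raise ValueError("population size must be >= 10")
    objectives = list(objectives or DEFAULT_OBJECTIVES)
    rng = np.random.default_rng(seed)
    template = gt.params

    cells: List[ParameterVector] = []
    rows = []
    feat_rows = []
    attempts = 0
    while len(cells) < n:
        if attempts > max_resample * n + n:
            raise SearchError("too many virtual cells failed normalization")
        attempts += 1
        factors = np.exp(rng.normal(0.0, jitter, size=len(template)))
        vals = np.clip(template.values * factors, template.lower, template.upper)
        pv = template.with_values(vals)
        gt_jit = GroundTruthModel(gt.etype, pv, gt.morphology, gt.config)
        cell = gt_jit.build(reduced=reduced)
        try:
            ih_t = find_holding(cell, V_TONIC)
            ih_b = find_holding(cell, V_BURST)
            thr = find_rheobase(cell, ih_t)
        except (SearchError, SimulationError) as exc:
            log.info("virtual cell resampled (%s)", exc)
            continue
        battery = make_battery(thr, ih_t, ih_b)
        feats = evaluate_objectives(cell, battery, objectives,
                                    noise_sd=noise_sd, rng=rng)
        cells.append(pv)
        rows.append((thr, ih_t, ih_b))
        feat_rows.append(feats)

    currents = pd.DataFrame(rows, columns=["i_thr", "i_hold_tonic", "i_hold_burst"])
    features = pd.DataFrame(
        [{f"{p}|{f}": v for (p, f), v in fr.items()} for fr in feat_rows]
    )

    targets: List[FeatureTarget] = []
    for proto_name, feat in objectives:
        col = features[f"{proto_name}|{feat}"]
        vals = col.dropna().astype(float)
        if len(vals) < n / 2:  # mostly undefined: not a usable constraint
            log.info("dropping target %s|%s (undefined for %d/%d cells)",
                     proto_name, feat, n - len(vals), n)
            continue
        mean = float(vals.mean())
        std = max(float(vals.std(ddof=1)), _std_floor(feat, mean))
        mode = "burst" if "Burst" in proto_name else "tonic"
        targets.append(FeatureTarget(feat, proto_name, mode, mean, std))

    ts = TargetSet(targets, float(currents.i_thr.mean()),
                   float(currents.i_hold_tonic.mean()),
                   float(currents.i_hold_burst.mean()), etype=gt.etype)
    return VirtualPopulation(gt.etype, cells, currents, features, ts)


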