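"""Electrical feature extraction, target sets, objective errors, e-types.

Features are extracted from somatic voltage traces relative to each
protocol's stimulus window.  Undefined features (e.g. spike-dependent
features on a silent trace) are reported as ``None``, never silently
zero; the objective-error step maps them to a large finite penalty so
model ranking stays total.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cell.simulate import Trace

__all__ = [
    "SpikeTrain",
    "FeatureTarget",
    "TargetSet",
    "detect_spikes",
    "adaptation_index",
    "classify_etype",
    "extract_features",
    "input_resistance",
    "objective_errors",
    "rank_models",
    "AI_CUTOFF",
    "PENALTY_ERROR",
    "FEATURE_NAMES",
]

AI_CUTOFF = 0.029  # adapting (cAD_ltb) at AI >= cutoff, else cNAD_ltb
PENALTY_ERROR = 250.0
SPIKE_DETECT_THRESHOLD = -20.0  # mV
DVDT_THRESHOLD = 20.0  # mV/ms: defines the per-spike threshold voltage

FEATURE_NAMES = (
    "spike_count",
    "mean_frequency",
    "time_to_first_spike",
    "adaptation_index",
    "inv_first_ISI",
    "inv_last_ISI",
    "ISI_mean",
    "AP_amplitude",
    "AP_half_width",
    "AHP_depth",
    "voltage_base",
    "steady_state_voltage",
    "sag_amplitude",
)


@dataclass
class SpikeTrain:
    """Detected spikes: times are threshold-crossing times [ms]."""

    times: np.ndarray
    peaks: np.ndarray  # mV
    thresholds: np.ndarray  # mV, at the dV/dt criterion
    half_widths: np.ndarray  # ms
    trough_after: np.ndarray  # mV, minimum before the next spike (or nan)

    def __post_init__(self):
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self):
        return len(self.times)

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


def detect_spikes(trace: Trace, threshold: float = SPIKE_DETECT_THRESHOLD) -> SpikeTrain:
    """Detect spikes as upward crossings of the detection threshold.

    A spike must come back below threshold before the next one can
    start, which merges double crossings, and its upstroke must exceed
    20 mV/ms (slow passive depolarizations through the detection
    threshold are not action potentials); the per-spike threshold
    voltage is the point before the peak where dV/dt first exceeds
    that criterion.
    """
    v = trace.v
    t = trace.t
    above = v >= threshold
    ups = np.nonzero(~above[:-1] & above[1:])[0] + 1
    downs = np.nonzero(above[:-1] & ~above[1:])[0] + 1
    times, peaks, thrs, hws, troughs = [], [], [], [], []
    dvdt = np.gradient(v, t)
    for k, iu in enumerate(ups):
        idn = downs[np.searchsorted(downs, iu)] if np.searchsorted(downs, iu) < len(downs) else len(v) - 1
        seg = slice(iu, max(idn + 1, iu + 2))
        ipk = iu + int(np.argmax(v[seg]))
        if np.max(dvdt[max(iu - 1, 0):ipk + 1]) < DVDT_THRESHOLD:
            continue  # slow crossing, not an action potential
        # threshold voltage: walk back from the peak into the upstroke,
        # then to the point where dV/dt first exceeded the criterion
        j = ipk
        while j > 0 and dvdt[j] <= DVDT_THRESHOLD:
            j -= 1
        while j > 0 and dvdt[j] > DVDT_THRESHOLD:
            j -= 1
        vthr = v[j]
        # half width at half amplitude between threshold and peak
        vhalf = 0.5 * (vthr + v[ipk])
        j0 = ipk
        while j0 > 0 and v[j0] > vhalf:
            j0 -= 1
        j1 = ipk
        while j1 < len(v) - 1 and v[j1] > vhalf:
            j1 += 1
        hw = t[j1] - t[j0]
        # trough before next spike
        inext = ups[k + 1] if k + 1 < len(ups) else len(v) - 1
        trough = float(np.min(v[ipk:inext + 1])) if inext > ipk else np.nan
        times.append(t[iu])
        peaks.append(float(v[ipk]))
        thrs.append(float(vthr))
        hws.append(float(hw))
        troughs.append(trough)
    return SpikeTrain(
        np.asarray(times), np.asarray(peaks), np.asarray(thrs),
        np.asarray(hws), np.asarray(troughs),
    )


def adaptation_index(train: SpikeTrain) -> Optional[float]:
    """Mean of (ISI_{i+1} - ISI_i) / (ISI_{i+1} + ISI_i); >= 3 spikes.

    Positive for lengthening ISIs (adapting discharge), zero for a
    perfectly regular train; ``None`` when fewer than three spikes.
    """
    if len(train) < 3:
        return None
    isi = train.isis()
    return float(np.mean((isi[1:] - isi[:-1]) / (isi[1:] + isi[:-1])))


def classify_etype(ai_values: Sequence[float], refit_min: int = 20,
                   random_state: int = 0):
    """Label adaptation-index values as cAD_ltb / cNAD_ltb.

    With >= ``refit_min`` values a two-component univariate Gaussian
    mixture is refit and the cutoff becomes the equal-posterior point
    between the component means; otherwise (or for a degenerate
    mixture whose means are closer than a quarter of the pooled SD)
    the fixed cutoff 0.029 is used.  Returns (labels, cutoff).
    """
    ai = np.asarray(ai_values, dtype=float)
    cutoff = AI_CUTOFF
    if len(ai) >= refit_min:
        from sklearn.mixture import GaussianMixture

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter on odd data
            gm = GaussianMixture(n_components=2, random_state=random_state,
                                 n_init=3)
            gm.fit(ai.reshape(-1, 1))
        mu = np.sort(gm.means_.ravel())
        pooled_sd = float(np.sqrt(np.mean(gm.covariances_.ravel())))
        if abs(mu[1] - mu[0]) < pooled_sd / 4.0 or np.min(gm.weights_) < 0.05:
            warnings.warn("degenerate mixture; using fixed AI cutoff", stacklevel=2)
        else:
            grid = np.linspace(mu[0], mu[1], 2001)
            post = gm.predict_proba(grid.reshape(-1, 1))
            hi = int(np.argmax(gm.means_.ravel()))
            cutoff = float(grid[np.argmin(np.abs(post[:, hi] - 0.5))])
    labels = np.where(ai >= cutoff, "cAD_ltb", "cNAD_ltb")
    return labels, cutoff


def _stim_window(protocol) -> Optional[Tuple[float, float]]:
    return getattr(protocol, "stim_window", None)


def extract_features(trace: Trace, protocol, names: Iterable[str],
                     threshold: float = SPIKE_DETECT_THRESHOLD) -> Dict[str, Optional[float]]:
    """Extract named features from one trace.

    Deterministic; undefined features come back as ``None``.  Windowed
    quantities are measured relative to the protocol's first stimulus
    segment; ``voltage_base`` uses the pre-stimulus interval (or the
    trace tail for unstimulated protocols).
    """
    names = list(names)
    unknown = set(names) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    win = _stim_window(protocol)
    train_all = detect_spikes(trace, threshold=threshold)
    if win is not None:
        t0, t1 = win
        m = (train_all.times >= t0) & (train_all.times <= t1)
        train = SpikeTrain(train_all.times[m], train_all.peaks[m],
                           train_all.thresholds[m], train_all.half_widths[m],
                           train_all.trough_after[m])
        base_mask = (trace.t >= max(0.0, t0 - 300.0)) & (trace.t <= t0 - 50.0)
        if not np.any(base_mask):
            base_mask = trace.t <= t0
        ss_mask = (trace.t >= t1 - 100.0) & (trace.t <= t1)
        stim_dur_s = (t1 - t0) / 1000.0
    else:
        t0, t1 = float(trace.t[0]), float(trace.t[-1])
        train = train_all
        base_mask = trace.t >= 0.8 * trace.t[-1]
        ss_mask = base_mask
        stim_dur_s = (t1 - t0) / 1000.0
    vbase = float(np.mean(trace.v[base_mask]))

    out: Dict[str, Optional[float]] = {}
    for name in names:
        if name == "spike_count":
            out[name] = float(len(train))
        elif name == "mean_frequency":
            out[name] = len(train) / stim_dur_s
        elif name == "time_to_first_spike":
            out[name] = float(train.times[0] - t0) if len(train) else None
        elif name == "adaptation_index":
            out[name] = adaptation_index(train)
        elif name == "inv_first_ISI":
            out[name] = 1000.0 / float(train.isis()[0]) if len(train) >= 2 else None
        elif name == "inv_last_ISI":
            out[name] = 1000.0 / float(train.isis()[-1]) if len(train) >= 2 else None
        elif name == "ISI_mean":
            out[name] = float(np.mean(train.isis())) if len(train) >= 2 else None
        elif name == "AP_amplitude":
            out[name] = float(np.mean(train.peaks - train.thresholds)) if len(train) else None
        elif name == "AP_half_width":
            out[name] = float(np.mean(train.half_widths)) if len(train) else None
        elif name == "AHP_depth":
            ok = ~np.isnan(train.trough_after) if len(train) else np.array([], bool)
            out[name] = float(np.mean(vbase - train.trough_after[ok])) if np.any(ok) else None
        elif name == "voltage_base":
            out[name] = vbase
        elif name == "steady_state_voltage":
            out[name] = float(np.mean(trace.v[ss_mask]))
        elif name == "sag_amplitude":
            if win is None:
                out[name] = None
            else:
                in_win = (trace.t >= t0) & (trace.t <= t1)
                vss = float(np.mean(trace.v[(trace.t >= t1 - 100.0) & (trace.t <= t1)]))
                vmin = float(np.min(trace.v[in_win]))
                out[name] = vss - vmin
    return out


def input_resistance(points: Sequence[Tuple[float, float]]) -> float:
    """Input resistance [MOhm] from (I [nA], V_ss [mV]) subthreshold points.

    Least-squares slope of the V-I relation; with mV over nA the slope
    is directly in MOhm.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least two (I, V) points")
    slope = np.polyfit(pts[:, 0], pts[:, 1], 1)[0]
    return float(slope)


@dataclass
class FeatureTarget:
    """Experimental-style target: mean and STD of one feature."""

    feature: str
    protocol: str
    mode: str
    mean: float
    std: float

    def __post_init__(self):
        if self.std <= 0:
            raise ValueError(f"{self.feature}@{self.protocol}: STD must be > 0")


@dataclass
class TargetSet:
    """A table of feature targets plus the stimulus normalization currents."""

    targets: List[FeatureTarget]
    i_thr: float
    i_hold_tonic: float
    i_hold_burst: float
    etype: str = ""

    def __iter__(self):
        return iter(self.targets)

    def __len__(self):
        return len(self.targets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.feature, t.protocol, t.mode, t.mean, t.std) for t in self.targets],
            columns=["feature", "protocol", "mode", "mean", "std"],
        )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# i_thr={self.i_thr!r} i_hold_tonic={self.i_hold_tonic!r} "
                     f"i_hold_burst={self.i_hold_burst!r} etype={self.etype}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TargetSet":
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh)
        kv = dict(tok.split("=") for tok in header.lstrip("# ").split())
        targets = [FeatureTarget(r.feature, r.protocol, r.mode, r["mean"], r["std"])
                   for _, r in df.iterrows()]
        return cls(targets, float(kv["i_thr"]), float(kv["i_hold_tonic"]),
                   float(kv["i_hold_burst"]), kv.get("etype", ""))


def objective_errors(model_features: Dict[Tuple[str, str], Optional[float]],
                     targets: TargetSet,
                     penalty: float = PENALTY_ERROR) -> Dict[Tuple[str, str], float]:
    """z-scored errors |value - mean| / STD per (protocol, feature).

    Undefined model features (no spikes where spikes are expected)
    receive the penalty error.
    """
    errors: Dict[Tuple[str, str], float] = {}
    for tgt in targets:
        key = (tgt.protocol, tgt.feature)
        val = model_features.get(key)
        if val is None:
            errors[key] = penalty
        else:
            errors[key] = abs(val - tgt.mean) / tgt.std
    return errors


def rank_models(error_sets: Sequence[Dict]) -> List[int]:
    """Order model indices ascending by max error, then sum, then input order."""
    keyed = [
        (max(e.values()) if e else np.inf, sum(e.values()), i)
        for i, e in enumerate(error_sets)
    ]
    return [i for _, _, i in sorted(keyed)]
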