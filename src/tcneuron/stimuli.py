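"""The e-code stimulus battery and per-cell normalization searches.

All stimulus amplitudes are expressed as percentages of the rheobase
current I_thr, so the same battery adapts to cells of different
excitability.  Two holding currents put the cell in tonic mode
(target -64 mV) or burst mode (target -84 mV); both targets are
liquid-junction-potential-corrected values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional

import numpy as np

from .cell.model import CellModel
from .cell.simulate import Trace, simulate

__all__ = [
    "Protocol",
    "ECodeBattery",
    "SearchError",
    "make_battery",
    "find_holding",
    "find_rheobase",
    "ou_noise",
    "fi_curve",
    "calibrate_noise_scale",
    "make_noise_protocol",
    "V_TONIC",
    "V_BURST",
]

V_TONIC = -64.0  # mV, LJP-corrected tonic-mode holding target
V_BURST = -84.0  # mV, LJP-corrected burst-mode holding target
ONSET_DELAY = 800.0  # ms


class SearchError(RuntimeError):
    pass


@dataclass
class Protocol:
    """A stimulus: holding current plus waveform segments.

    Segment dicts: ``{"kind": "step", "amp": nA, "t0": ms, "t1": ms}``,
    ``{"kind": "ramp", "amp0": nA, "amp1": nA, "t0": ms, "t1": ms}`` or
    ``{"kind": "noise", "samples": array nA, "dt": ms, "t0": ms,
    "seed": int}``.  Segment times are absolute (the onset delay is
    already folded in at construction) and non-overlapping.
    """

    name: str
    holding: float
    segments: List[Dict]
    duration: float
    onset_delay: float = ONSET_DELAY
    mode: str = "tonic"  # tonic | burst
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        spans = sorted((s["t0"], s["t1"]) for s in self.segments)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"protocol {self.name}: overlapping segments")

    @property
    def stim_window(self):
        """(t0, t1) of the first waveform segment, or None."""
        if not self.segments:
            return None
        s = self.segments[0]
        return (s["t0"], s["t1"])

    def to_dict(self) -> Dict:
        """Plain-data form for structured-text serialization.

        Noise segments store their seed and parameters; samples are
        regenerated on load, so the replay is exact without shipping
        the sample vector.
        """
        segments = []
        for seg in self.segments:
            seg = dict(seg)
            if seg["kind"] == "noise":
                seg.pop("samples")
            segments.append(seg)
        return {"name": self.name, "holding": self.holding,
                "segments": segments, "duration": self.duration,
                "onset_delay": self.onset_delay, "mode": self.mode}

    @classmethod
    def from_dict(cls, doc: Dict, w: Optional[float] = None,
                  offset: float = 1.0) -> "Protocol":
        segments = []
        for seg in doc["segments"]:
            seg = dict(seg)
            if seg["kind"] == "noise":
                sample = ou_noise(seg["dt"], seg["t1"] - seg["t0"],
                                  tau=seg["tau"], sigma=seg["sigma"],
                                  seed=seg["seed"])
                seg["samples"] = seg.get("w", w or 1.0) * (offset + sample)
            segments.append(seg)
        return cls(name=doc["name"], holding=doc["holding"],
                   segments=segments, duration=doc["duration"],
                   onset_delay=doc.get("onset_delay", ONSET_DELAY),
                   mode=doc.get("mode", "tonic"))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "Protocol":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def current_array(self, dt: float, nsteps: Optional[int] = None) -> np.ndarray:
        n = nsteps if nsteps is not None else int(round(self.duration / dt))
        out = np.full(n, self.holding, dtype=float)
        t = (np.arange(n) + 0.5) * dt  # midpoint of each step interval
        for seg in self.segments:
            m = (t >= seg["t0"]) & (t < seg["t1"])
            if seg["kind"] == "step":
                out[m] += seg["amp"]
            elif seg["kind"] == "ramp":
                frac = (t[m] - seg["t0"]) / (seg["t1"] - seg["t0"])
                out[m] += seg["amp0"] + (seg["amp1"] - seg["amp0"]) * frac
            elif seg["kind"] == "noise":
                samples = np.asarray(seg["samples"], dtype=float)
                k = np.minimum(
                    ((t[m] - seg["t0"]) / seg["dt"]).astype(int), len(samples) - 1
                )
                out[m] += samples[k]
            else:
                raise ValueError(f"unknown segment kind {seg['kind']!r}")
        return out


def _step(name, holding, amp, dur, mode, tail=250.0, meta=None):
    return Protocol(
        name=name,
        holding=holding,
        segments=[{"kind": "step", "amp": amp, "t0": ONSET_DELAY, "t1": ONSET_DELAY + dur}],
        duration=ONSET_DELAY + dur + tail,
        mode=mode,
        meta=meta or {},
    )


@dataclass
class ECodeBattery:
    """The full protocol set generated from I_thr and the two holdings."""

    i_thr: float
    i_hold_tonic: float
    i_hold_burst: float
    protocols: Dict[str, Protocol] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Protocol:
        return self.protocols[name]

    def names(self) -> List[str]:
        return list(self.protocols)


def make_battery(i_thr: float, i_hold_tonic: float, i_hold_burst: float,
                 spon_duration: float = 2500.0) -> ECodeBattery:
    """Generate the e-code from the rheobase and the two holding currents.

    Amplitudes are exact rational multiples of I_thr (Fraction
    arithmetic, no float drift in the percentages).  Step protocols in
    burst mode mirror the tonic step set but ride on the burst holding.
    """
    if i_thr <= 0:
        raise ValueError("i_thr must be > 0")
    protos: Dict[str, Protocol] = {}

    def amp(pct: int) -> float:
        return float(Fraction(pct, 100) * Fraction(i_thr))

    for pct in range(50, 301, 25):  # IDRest / Step: 1350 ms, 25% increments
        protos[f"Step_{pct}"] = _step(
            f"Step_{pct}", i_hold_tonic, amp(pct), 1350.0, "tonic",
            meta={"pct": pct})
        protos[f"StepBurst_{pct}"] = _step(
            f"StepBurst_{pct}", i_hold_burst, amp(pct), 1350.0, "burst",
            meta={"pct": pct})
    for pct in range(50, 131, 4):  # IDThresh: 270 ms, 4% increments
        protos[f"IDThresh_{pct}"] = _step(
            f"IDThresh_{pct}", i_hold_tonic, amp(pct), 270.0, "tonic",
            meta={"pct": pct})
    for pct in range(-140, 61, 20):  # IV: 3000 ms, 20% increments
        protos[f"IV_{pct}"] = _step(
            f"IV_{pct}", i_hold_tonic, amp(pct), 3000.0, "tonic",
            meta={"pct": pct})

    # PosCheops: three up-down ramp pairs (4000, 2000, 1250 ms) to 300%
    for mode, hold in (("tonic", i_hold_tonic), ("burst", i_hold_burst)):
        t = ONSET_DELAY
        segs = []
        for dur in (4000.0, 2000.0, 1250.0):
            segs.append({"kind": "ramp", "amp0": 0.0, "amp1": amp(300),
                         "t0": t, "t1": t + dur})
            segs.append({"kind": "ramp", "amp0": amp(300), "amp1": 0.0,
                         "t0": t + dur, "t1": t + 2 * dur})
            t += 2 * dur
        name = "PosCheops" if mode == "tonic" else "PosCheopsBurst"
        protos[name] = Protocol(name=name, holding=hold, segments=segs,
                                duration=t + 250.0, mode=mode)

    # Single-ramp protocols used for generalization testing: tonic mode
    # uses the first (slowest) ascending ramp, burst mode the last
    # (fastest), each to 300% threshold.
    protos["RampTonic"] = Protocol(
        name="RampTonic", holding=i_hold_tonic,
        segments=[{"kind": "ramp", "amp0": 0.0, "amp1": amp(300),
                   "t0": ONSET_DELAY, "t1": ONSET_DELAY + 4000.0}],
        duration=ONSET_DELAY + 4000.0 + 250.0, mode="tonic")
    protos["RampBurst"] = Protocol(
        name="RampBurst", holding=i_hold_burst,
        segments=[{"kind": "ramp", "amp0": 0.0, "amp1": amp(300),
                   "t0": ONSET_DELAY, "t1": ONSET_DELAY + 1250.0}],
        duration=ONSET_DELAY + 1250.0 + 250.0, mode="burst")

    # Spontaneous-activity protocols carry a zero-amplitude "stimulus"
    # segment so that windowed features (spike count, steady state) are
    # measured after the initialization transient has settled.
    spon_seg = [{"kind": "step", "amp": 0.0, "t0": ONSET_DELAY,
                 "t1": spon_duration - 50.0}]
    protos["SponNoHold"] = Protocol(name="SponNoHold", holding=0.0,
                                    segments=list(spon_seg),
                                    duration=spon_duration, mode="tonic")
    protos["SponHold"] = Protocol(name="SponHold", holding=i_hold_tonic,
                                  segments=list(spon_seg),
                                  duration=spon_duration, mode="tonic")
    return ECodeBattery(i_thr, i_hold_tonic, i_hold_burst, protos)


def find_holding(cell: CellModel, v_target: float, tol: float = 0.25,
                 settle: float = 2000.0, bracket: float = 2.0,
                 max_iter: int = 40) -> float:
    """Bisection on steady-state somatic voltage for the holding current.

    The steady state is read at the end of a ``settle``-ms constant
    injection; the search stops when it is within ``tol`` mV of the
    target.
    """
    if not (-100.0 <= v_target <= -40.0):
        raise ValueError("v_target must lie in [-100, -40] mV")
    from .cell.simulate import SimulationError, steady_state_voltage

    def f(i_hold: float) -> float:
        # extreme bracket currents may drive the cell out of range; that
        # still brackets the target, so map divergence to +-inf
        try:
            return steady_state_voltage(cell, i_hold, duration=settle) - v_target
        except SimulationError:
            if i_hold == 0.0:
                raise
            return np.inf * np.sign(i_hold)

    lo, hi = -bracket, bracket
    if f(lo) > 0 or f(hi) < 0:
        raise SearchError(
            f"holding bracket [-{bracket}, {bracket}] nA does not contain "
            f"v_target = {v_target} mV"
        )
    mid = 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) < tol:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    raise SearchError(f"holding search did not converge to {v_target} mV")


def _spike_count(trace: Trace, t0: float, t1: float, threshold: float = -20.0) -> int:
    from .efeatures import detect_spikes

    train = detect_spikes(trace, threshold=threshold)
    return int(np.sum((train.times >= t0) & (train.times <= t1)))


def find_rheobase(cell: CellModel, i_hold: float, resolution: float = 0.001,
                  i_max: float = 2.0, step_dur: float = 1350.0) -> float:
    """Minimal 1350-ms step amplitude (on holding) evoking >= 1 spike.

    Coarse geometric scan to bracket, then bisection to ``resolution``
    nA (1 pA).  The returned amplitude spikes; amplitude - 1 pA does
    not (up to the bisection tolerance).
    """

    from .cell.simulate import SimulationError

    def spikes(amp: float) -> int:
        proto = _step("rheo", i_hold, amp, step_dur, "tonic")
        try:
            tr = simulate(cell, proto)
        except SimulationError:
            # runaway depolarization without spikes (e.g. passive cell
            # driven out of range) is not an excitable response
            return 0
        return _spike_count(tr, ONSET_DELAY, ONSET_DELAY + step_dur)

    lo = 0.0
    hi = None
    for amp in (0.0125, 0.025, 0.05, 0.1, 0.2, 0.4, 0.8, 1.2, 1.6, 2.0):
        if amp > i_max:
            break
        if spikes(amp) >= 1:
            hi = amp
            break
        lo = amp
    if hi is None:
        raise SearchError(f"no spiking up to {i_max} nA: cell not excitable")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if spikes(mid) >= 1:
            hi = mid
        else:
            lo = mid
    return hi


def ou_noise(dt: float, duration: float, tau: float = 3.0, sigma: float = 0.5,
             seed: int = 0) -> np.ndarray:
    """Exact-discretization Ornstein-Uhlenbeck sample (zero mean).

    x_{k+1} = x_k e^{-dt/tau} + sigma sqrt(1 - e^{-2 dt/tau}) xi_k,
    started from the stationary distribution; the sample is fully
    reproducible from the seed.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    b = sigma * np.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = sigma * rng.standard_normal()
    xi = rng.standard_normal(n - 1)
    for k in range(n - 1):
        x[k + 1] = x[k] * a + b * xi[k]
    return x


def fi_curve(cell: CellModel, battery: ECodeBattery):
    """(amplitudes nA, rates Hz) from the tonic Step protocols."""
    amps, rates = [], []
    for pct in range(50, 301, 25):
        proto = battery[f"Step_{pct}"]
        seg = proto.segments[0]
        tr = simulate(cell, proto)
        n = _spike_count(tr, seg["t0"], seg["t1"])
        amps.append(seg["amp"])
        rates.append(n / ((seg["t1"] - seg["t0"]) / 1000.0))
    return np.array(amps), np.array(rates)


def calibrate_noise_scale(cell_or_curve, battery: Optional[ECodeBattery] = None,
                          target_rate: float = 7.5) -> float:
    """Noise scaling factor w: the current that makes the cell fire at
    the calibration rate (7.5 Hz), linearly interpolated on the f-I curve.

    Accepts either a cell (+battery) or a precomputed ``(amps, rates)``
    pair.
    """
    if isinstance(cell_or_curve, CellModel):
        amps, rates = fi_curve(cell_or_curve, battery)
    else:
        amps, rates = map(np.asarray, cell_or_curve)
    above = np.nonzero(rates >= target_rate)[0]
    if len(above) == 0 or rates[above[0]] == 0:
        raise SearchError(f"f-I curve never reaches {target_rate} Hz")
    j = above[0]
    if j == 0:
        return float(amps[0])
    f0, f1 = rates[j - 1], rates[j]
    if f1 == f0:
        return float(amps[j])
    return float(amps[j - 1] + (target_rate - f0) * (amps[j] - amps[j - 1]) / (f1 - f0))


def make_noise_protocol(w: float, i_hold: float, duration: float = 3000.0,
                        dt: float = 0.025, tau: float = 3.0, sigma: float = 0.5,
                        offset: float = 1.0, seed: int = 0,
                        mode: str = "tonic") -> Protocol:
    """NOISEOU3-style protocol: holding + w * (offset + OU sample).

    The OU sample is stored with its seed and parameters, so the
    protocol replays bit-identically.
    """
    samples = w * (offset + ou_noise(dt, duration, tau=tau, sigma=sigma, seed=seed))
    return Protocol(
        name="NOISEOU3",
        holding=i_hold,
        segments=[{"kind": "noise", "samples": samples, "dt": dt,
                   "t0": ONSET_DELAY, "t1": ONSET_DELAY + duration,
                   "seed": seed, "tau": tau, "sigma": sigma, "w": w}],
        duration=ONSET_DELAY + duration + 250.0,
        mode=mode,
    )
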