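"""Multi-objective evolutionary fitting and model validation.

The fitter is an Indicator-Based Evolutionary Algorithm (IBEA) with
the additive-epsilon indicator, simulated binary crossover and bounded
polynomial mutation.  Each candidate parameter vector is scored by
simulating the stimulus battery and z-scoring the extracted features
against the target set; a model is *accepted* when every feature error
is strictly below the 3-STD threshold.

Validation beyond fitting: generalization to ramp and noise stimuli
(with a repetitive-burst screen), and e-model x morphology
("me-combination") testing with per-morphology re-normalization of
holding and rheobase currents.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cell.model import CellModel, ParameterVector
from .cell.simulate import SimulationError, simulate
from .efeatures import (
    PENALTY_ERROR,
    TargetSet,
    FeatureTarget,
    detect_spikes,
    extract_features,
    objective_errors,
    rank_models,
)
from .stimuli import (
    ECodeBattery,
    SearchError,
    V_BURST,
    V_TONIC,
    calibrate_noise_scale,
    find_holding,
    find_rheobase,
    make_battery,
    make_noise_protocol,
)
from .synthetic_data.population import evaluate_objectives

__all__ = [
    "OptimizationConfig",
    "EvaluatedIndividual",
    "OptimizationResult",
    "ibea_minimize",
    "run_optimization",
    "accept_models",
    "make_generalization_targets",
    "run_generalization",
    "me_combinations",
    "GENERALIZATION_OBJECTIVES",
]

log = logging.getLogger(__name__)


@dataclass
class OptimizationConfig:
    """IBEA hyperparameters and acceptance threshold.

    Defaults follow the full-scale protocol (100 individuals, 100
    generations, 3 seeds); the scaled-down profile used in CI-sized
    runs is 20 x 20 x 1 seed on the single-compartment reduction.
    """

    pop_size: int = 100
    generations: int = 100
    seeds: Tuple[int, ...] = (1, 2, 3)
    accept_threshold: float = 3.0
    kappa: float = 0.05  # indicator scaling
    eta_crossover: float = 15.0
    eta_mutation: float = 20.0
    p_crossover: float = 0.9
    objectives: Optional[Sequence[Tuple[str, str]]] = None
    free_names: Optional[Sequence[str]] = None
    checkpoint_dir: Optional[str] = None
    # Normalize the battery to each candidate's own holding currents and
    # rheobase, exactly as every experimental cell was normalized before
    # its features entered the targets.  Candidates whose searches fail
    # (inexcitable or diverging) score the penalty error.
    normalize_per_candidate: bool = True

    def scaled_down(self) -> "OptimizationConfig":
        """CI-sized profile: 20 individuals x 20 generations, one seed,
        meant for the single-compartment reduction.  At this budget the
        search is strongly initialization-dominated; see the methods
        note for what it can and cannot be expected to find."""
        from dataclasses import replace

        return replace(self, pop_size=20, generations=20, seeds=(1,))


@dataclass
class EvaluatedIndividual:
    params: ParameterVector
    errors: Dict[Tuple[str, str], float]

    @property
    def max_error(self) -> float:
        return max(self.errors.values()) if self.errors else np.inf

    @property
    def sum_error(self) -> float:
        return float(sum(self.errors.values()))


@dataclass
class OptimizationResult:
    archives: Dict[int, List[EvaluatedIndividual]] = field(default_factory=dict)
    accept_threshold: float = 3.0

    @property
    def evaluated(self) -> List[EvaluatedIndividual]:
        return [ind for arch in self.archives.values() for ind in arch]

    @property
    def accepted(self) -> List[EvaluatedIndividual]:
        return accept_models(self, self.accept_threshold)

    @property
    def best(self) -> EvaluatedIndividual:
        evs = self.evaluated
        order = rank_models([e.errors for e in evs])
        return evs[order[0]]


def _epsilon_indicator(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Pairwise additive epsilon indicator I(a, b) = max_i (fa_i - fb_i)."""
    return np.max(fa[:, None, :] - fb[None, :, :], axis=2)


def _ibea_fitness(F: np.ndarray, kappa: float) -> np.ndarray:
    """IBEA fitness: F(x) = sum_{y != x} -exp(-I(y, x) / (kappa c))."""
    eps = _epsilon_indicator(F, F)
    c = max(np.max(np.abs(eps)), 1e-12)
    E = -np.exp(-eps / (kappa * c))
    np.fill_diagonal(E, 0.0)
    return E.sum(axis=0)


def _sbx(rng, a, b, lower, upper, eta):
    """Simulated binary crossover, blend variant (one child).

    All coordinates are blended toward the first parent; at small
    population sizes this measured better than per-variable crossover,
    which fragments the few good building blocks available.
    """
    u = rng.random(len(a))
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    child = 0.5 * ((1 + beta) * a + (1 - beta) * b)
    return np.clip(child, lower, upper)


def _poly_mutate(rng, x, lower, upper, eta, p):
    y = x.copy()
    span = upper - lower
    for i in range(len(x)):
        if rng.random() < p and span[i] > 0:
            u = rng.random()
            if u < 0.5:
                delta = (2 * u) ** (1 / (eta + 1)) - 1
            else:
                delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
            y[i] = np.clip(x[i] + delta * span[i], lower[i], upper[i])
    return y


def ibea_minimize(
    evaluate: Callable[[np.ndarray], np.ndarray],
    lower: np.ndarray,
    upper: np.ndarray,
    pop_size: int = 20,
    generations: int = 20,
    seed: int = 1,
    kappa: float = 0.05,
    eta_crossover: float = 15.0,
    eta_mutation: float = 20.0,
    p_crossover: float = 0.9,
    log_uniform: Optional[np.ndarray] = None,
    map_fn: Callable = map,
    on_generation: Optional[Callable] = None,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Core IBEA loop over a box-bounded parameter space.

    ``evaluate`` maps a parameter vector to an objective vector (all
    minimized).  ``log_uniform`` marks coordinates that span orders of
    magnitude: they are sampled log-uniformly AND varied (crossover,
    mutation) in log space, so a mutation step means a fold-change
    rather than an absolute shift.  Returns the archive of every
    evaluated (x, objectives) pair, deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    n = len(lower)
    if log_uniform is None:
        log_uniform = np.zeros(n, dtype=bool)
    log_uniform = np.asarray(log_uniform, dtype=bool)

    # search coordinates: log10 for log-scale dims, identity otherwise
    t_lower = np.where(log_uniform, np.log10(np.maximum(lower, 1e-12)), lower)
    t_upper = np.where(log_uniform, np.log10(upper), upper)

    def to_x(z: np.ndarray) -> np.ndarray:
        return np.where(log_uniform, 10.0 ** z, z)

    def sample() -> np.ndarray:
        return rng.uniform(t_lower, t_upper)

    pop = [sample() for _ in range(pop_size)]
    objs = list(map_fn(evaluate, [to_x(z) for z in pop]))
    archive: List[Tuple[np.ndarray, np.ndarray]] = \
        [(to_x(z), f) for z, f in zip(pop, objs)]

    def normalize(F: np.ndarray) -> np.ndarray:
        # Min-max normalization with a winsorized upper end: outlier
        # objective values (failure penalties) would otherwise compress
        # the differences between viable individuals to nothing, leaving
        # selection to drift on rounding noise.
        fmin = F.min(axis=0)
        fcap = np.quantile(F, 0.9, axis=0)
        fcap = np.where(fcap > fmin, fcap, F.max(axis=0))
        span = np.where(fcap > fmin, fcap - fmin, 1.0)
        return np.clip((F - fmin) / span, 0.0, 1.0)

    for gen in range(generations):
        F = np.asarray(objs, float)
        Fn = normalize(F)
        fit = _ibea_fitness(Fn, kappa)

        def tournament():
            i, j = rng.integers(0, pop_size, 2)
            return pop[i] if fit[i] >= fit[j] else pop[j]

        children = []
        for _ in range(pop_size):
            a, b = tournament(), tournament()
            child = _sbx(rng, a, b, t_lower, t_upper, eta_crossover) \
                if rng.random() < p_crossover else a.copy()
            child = _poly_mutate(rng, child, t_lower, t_upper, eta_mutation,
                                 1.0 / n)
            children.append(child)
        child_objs = list(map_fn(evaluate, [to_x(z) for z in children]))
        archive.extend((to_x(z), f) for z, f in zip(children, child_objs))

        # environmental selection on the merged pool
        pool = pop + children
        pool_objs = objs + child_objs
        Fpn = normalize(np.asarray(pool_objs, float))
        eps = _epsilon_indicator(Fpn, Fpn)
        c = max(np.max(np.abs(eps)), 1e-12)
        E = -np.exp(-eps / (kappa * c))
        np.fill_diagonal(E, 0.0)
        fit_pool = E.sum(axis=0)
        alive = list(range(len(pool)))
        while len(alive) > pop_size:
            worst_pos = int(np.argmin(fit_pool[alive]))
            worst = alive.pop(worst_pos)
            # removing `worst` takes its contribution out of the others
            for i in alive:
                fit_pool[i] -= E[worst, i]
        pop = [pool[i] for i in alive]
        objs = [pool_objs[i] for i in alive]
        if on_generation is not None:
            on_generation(gen, archive, pop, objs)
    return archive


def _build_evaluator(template: CellModel, targets: TargetSet,
                     objectives: Sequence[Tuple[str, str]],
                     free_idx: np.ndarray,
                     normalize_per_candidate: bool = True):
    """Closure mapping a free-parameter vector to the error vector."""
    fixed_battery = make_battery(targets.i_thr, targets.i_hold_tonic,
                                 targets.i_hold_burst)
    keys = [(t.protocol, t.feature) for t in targets
            if (t.protocol, t.feature) in set(objectives)]
    base_values = template.params.values.copy()

    def evaluate(x: np.ndarray) -> np.ndarray:
        vals = base_values.copy()
        vals[free_idx] = x
        cell = template.with_params(template.params.with_values(vals))
        try:
            if normalize_per_candidate:
                ih_t = find_holding(cell, V_TONIC)
                ih_b = find_holding(cell, V_BURST)
                thr = find_rheobase(cell, ih_t)
                battery = make_battery(thr, ih_t, ih_b)
            else:
                battery = fixed_battery
            feats = evaluate_objectives(cell, battery, keys)
            errs = objective_errors(feats, targets)
        except (SimulationError, SearchError):
            return np.full(len(keys), PENALTY_ERROR)
        return np.array([errs[k] for k in keys])

    return evaluate, keys


def run_optimization(targets: TargetSet, template: CellModel,
                     cfg: Optional[OptimizationConfig] = None,
                     map_fn: Callable = map) -> OptimizationResult:
    """Fit the template cell's free parameters to the target set.

    ``map_fn`` is the pluggable parallel-map contract: order
    preserving, exception propagating; the default is serial.  Each
    seed runs an independent IBEA; every evaluation enters the
    archive.  Simulation failures score the penalty error instead of
    raising.
    """
    cfg = cfg or OptimizationConfig()
    objectives = list(cfg.objectives or [(t.protocol, t.feature) for t in targets])
    names = list(template.params.names)
    free_names = list(cfg.free_names or
                      [n for n in names if not n.endswith(".unused")])
    free_idx = np.array([names.index(n) for n in free_names])
    lower = template.params.lower[free_idx]
    upper = template.params.upper[free_idx]
    # conductances/permeabilities span orders of magnitude -> log-uniform
    log_mask = np.array([n.split(".")[0] not in ("gamma_Ca", "tau_Ca")
                         for n in free_names])
    evaluate, keys = _build_evaluator(template, targets, objectives, free_idx,
                                      cfg.normalize_per_candidate)

    result = OptimizationResult(accept_threshold=cfg.accept_threshold)
    for seed in cfg.seeds:
        ckpt = None
        if cfg.checkpoint_dir:
            ckpt_path = Path(cfg.checkpoint_dir) / f"archive_seed{seed}.json"
            ckpt_path.parent.mkdir(parents=True, exist_ok=True)

            def ckpt(gen, archive, pop, objs, _p=ckpt_path, _s=seed):
                payload = {
                    "seed": _s, "generation": gen,
                    "archive": [[list(map(float, x)), list(map(float, f))]
                                 for x, f in archive],
                }
                _p.write_text(json.dumps(payload))

        archive = ibea_minimize(
            evaluate, lower, upper,
            pop_size=cfg.pop_size, generations=cfg.generations, seed=seed,
            kappa=cfg.kappa, eta_crossover=cfg.eta_crossover,
            eta_mutation=cfg.eta_mutation, p_crossover=cfg.p_crossover,
            log_uniform=log_mask, map_fn=map_fn, on_generation=ckpt,
        )
        inds = []
        for x, f in archive:
            vals = template.params.values.copy()
            vals[free_idx] = x
            errors = dict(zip(keys, map(float, f)))
            inds.append(EvaluatedIndividual(template.params.with_values(vals),
                                            errors))
        result.archives[seed] = inds
    return result


def accept_models(result: OptimizationResult,
                  threshold: float = 3.0) -> List[EvaluatedIndividual]:
    """Models with ALL feature errors strictly below the threshold."""
    return [ind for ind in result.evaluated if ind.max_error < threshold]


GENERALIZATION_OBJECTIVES: List[Tuple[str, str]] = [
    ("RampTonic", "time_to_first_spike"),
    ("RampTonic", "spike_count"),
    ("RampBurst", "spike_count"),
    ("NOISEOU3", "spike_count"),
]


def _generalization_features(cell: CellModel, battery: ECodeBattery,
                             noise_seed: int = 0):
    """Ramp and noise features used only for generalization testing."""
    feats = evaluate_objectives(
        cell, battery,
        [(p, f) for p, f in GENERALIZATION_OBJECTIVES if p != "NOISEOU3"])
    w = calibrate_noise_scale(cell, battery)
    noise = make_noise_protocol(w, battery.i_hold_tonic, seed=noise_seed)
    tr = simulate(cell, noise)
    vals = extract_features(tr, noise, ["spike_count"])
    feats[("NOISEOU3", "spike_count")] = vals["spike_count"]
    return feats


def make_generalization_targets(gt_cell: CellModel, i_thr: float,
                                i_hold_tonic: float, i_hold_burst: float,
                                noise_seed: int = 0, rel_std: float = 0.2) -> TargetSet:
    """Generalization targets from a reference cell's own responses.

    STDs are a fixed fraction of each mean (floored), standing in for
    population variability on the held-out stimuli.
    """
    battery = make_battery(i_thr, i_hold_tonic, i_hold_burst)
    feats = _generalization_features(gt_cell, battery, noise_seed=noise_seed)
    targets = []
    for (proto, feat), val in feats.items():
        if val is None:
            continue
        std = max(rel_std * abs(val), 1.0)
        mode = "burst" if proto == "RampBurst" else "tonic"
        targets.append(FeatureTarget(feat, proto, mode, float(val), std))
    return TargetSet(targets, i_thr, i_hold_tonic, i_hold_burst)


def count_burst_events(spike_times: np.ndarray, intra_isi: float = 30.0) -> int:
    """Number of burst events in a spike train.

    Spikes separated by less than ``intra_isi`` ms belong to the same
    event; an event with >= 2 spikes is a burst.  Single isolated
    spikes (tonic-like discharge) do not count.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if len(spike_times) < 2:
        return 0
    groups = np.split(spike_times,
                      np.nonzero(np.diff(spike_times) >= intra_isi)[0] + 1)
    return sum(1 for g in groups if len(g) >= 2)


def run_generalization(cell: CellModel, gen_targets: TargetSet,
                       threshold: float = 3.0, noise_seed: int = 0):
    """Generalization errors on ramps + noise, plus the burst screen.

    The model was fit on current steps only; here it faces ramps and a
    noise stimulus.  Burst-mode ramp responses with more than one burst
    event (repetitive bursting, never seen in recordings) fail the
    screen regardless of feature errors.  Returns (errors, passed).
    """
    battery = make_battery(gen_targets.i_thr, gen_targets.i_hold_tonic,
                           gen_targets.i_hold_burst)
    try:
        feats = _generalization_features(cell, battery, noise_seed=noise_seed)
    except (SimulationError, SearchError):
        keys = [(t.protocol, t.feature) for t in gen_targets]
        return {k: PENALTY_ERROR for k in keys}, False
    errors = objective_errors(feats, gen_targets)
    ramp_burst = battery["RampBurst"]
    tr = simulate(cell, ramp_burst)
    st = detect_spikes(tr)
    w0, w1 = ramp_burst.stim_window
    times = st.times[(st.times >= w0) & (st.times <= w1)]
    repetitive = count_burst_events(times) > 1
    passed = (not repetitive) and all(e < threshold for e in errors.values())
    return errors, passed


def me_combinations(e_models: Dict[str, ParameterVector],
                    morphologies: Sequence,
                    targets_by_model: Dict[str, TargetSet],
                    objectives: Optional[Sequence[Tuple[str, str]]] = None,
                    threshold: float = 3.0,
                    build_fn: Optional[Callable] = None,
                    map_fn: Callable = map):
    """Evaluate every e-model on every morphology with re-normalization.

    For each morphology the holding currents (tonic -64 mV, burst
    -84 mV) and the rheobase are searched afresh, the battery is
    rebuilt on them, and the optimization feature errors are recomputed
    against each e-model's targets.  Per morphology the e-model with
    the smallest maximum error is selected; the combination is accepted
    when that error is below the threshold.  Failed searches mark the
    combination with the failure reason instead of raising.
    """
    from .cell.model import build_cell

    build_fn = build_fn or (lambda morph, pv: build_cell(morph, params=pv))

    def eval_combo(args):
        mi, morph = args
        row = {"morphology": getattr(morph, "name", str(mi))}
        best_err = np.inf
        best_model = None
        for mname, pv in e_models.items():
            tset = targets_by_model[mname]
            objs = list(objectives or [(t.protocol, t.feature) for t in tset])
            try:
                cell = build_fn(morph, pv)
                ih_t = find_holding(cell, V_TONIC)
                ih_b = find_holding(cell, V_BURST)
                thr = find_rheobase(cell, ih_t)
                battery = make_battery(thr, ih_t, ih_b)
                feats = evaluate_objectives(cell, battery, objs)
                errs = objective_errors(feats, tset)
                emax = max(errs[k] for k in objs if k in errs)
            except (SearchError, SimulationError) as exc:
                row[f"error_{mname}"] = None
                row.setdefault("failure", f"{mname}: {exc}")
                continue
            row[f"error_{mname}"] = emax
            if emax < best_err:
                best_err, best_model = emax, mname
        row["best_model"] = best_model
        row["best_max_error"] = best_err if best_model else None
        row["accepted"] = bool(best_model and best_err < threshold)
        return row

    rows = list(map_fn(eval_combo, list(enumerate(morphologies))))
    import pandas as pd

    return pd.DataFrame(rows)
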