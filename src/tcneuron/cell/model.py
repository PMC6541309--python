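"""Cell model assembly: channel distributions, free parameters, config.

The default free-parameter layout has exactly 22 entries: per-region
peak conductances/permeabilities named ``<param>.<region-initial>``
(".s" soma, ".d" dendrites, ".a" axon), with the T-type calcium
permeability shared between soma and dendrites (".sd"), plus the two
calcium-dynamics parameters gamma_Ca and tau_Ca.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from ..channels import CaDynamics, ChannelSpec, default_channels
from .discretize import CompartmentGraph, discretize
from .morphology import Morphology, replace_axon_with_stub

__all__ = [
    "SimConfig",
    "ParameterVector",
    "RegionDistribution",
    "CellModel",
    "build_cell",
    "single_compartment_reduction",
    "DEFAULT_BOUNDS",
    "default_parameter_vector",
    "default_distribution",
]


@dataclass
class SimConfig:
    """Global simulation constants (overridable)."""

    temperature: float = 34.0  # degC
    cm: float = 1.0  # uF/cm^2
    ra: float = 100.0  # Ohm cm
    v_init: float = -79.0  # mV
    e_na: float = 50.0  # mV
    e_k: float = -90.0  # mV
    seg_len: float = 40.0  # um
    dt: float = 0.025  # ms
    theta: float = 0.5  # 0.5 Crank-Nicolson, 1.0 backward Euler
    onset_delay: float = 800.0  # ms, stimulus onset after initialization


class ValidationError(ValueError):
    pass


@dataclass
class ParameterVector:
    """Ordered named free parameters with bounds.

    Conductances are S/cm^2, permeabilities cm/s, gamma_Ca is
    dimensionless, tau_Ca is ms.
    """

    names: List[str]
    values: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        n = len(self.names)
        if not (len(self.values) == len(self.lower) == len(self.upper) == n):
            raise ValidationError("parameter vector arrays must share one length")

    def __len__(self):
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values))

    def with_values(self, values) -> "ParameterVector":
        return ParameterVector(self.names, np.asarray(values, dtype=float),
                               self.lower, self.upper)

    def with_updates(self, updates: Mapping[str, float]) -> "ParameterVector":
        vals = self.values.copy()
        for k, v in updates.items():
            vals[self.names.index(k)] = v
        return self.with_values(vals)

    def validate(self, expected_count: Optional[int] = 22) -> None:
        if expected_count is not None and len(self) != expected_count:
            raise ValidationError(
                f"default configuration requires exactly {expected_count} free "
                f"parameters, got {len(self)}"
            )
        bad = [
            f"{n}={v:g} not in [{lo:g}, {hi:g}]"
            for n, v, lo, hi in zip(self.names, self.values, self.lower, self.upper)
            if not (lo <= v <= hi)
        ]
        if bad:
            raise ValidationError("parameters out of bounds: " + "; ".join(bad))


# Wide default bounds; conductance/permeability ranges span orders of
# magnitude, so optimization samples them log-uniformly.
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "conductance": (1e-7, 1.0),  # S/cm^2
    "permeability": (1e-7, 1e-2),  # cm/s
    "gamma_Ca": (0.001, 0.05),
    "tau_Ca": (20.0, 300.0),
}

# Per-channel search ranges for optimization, analogous to the
# per-parameter initial ranges used when fitting against recordings:
# each current is searched over the span physiologically plausible for
# it (spike currents are dense, subthreshold currents sparse) instead
# of the maximally agnostic default bounds.  Keys are channel ids.
SEARCH_BOUNDS: Dict[str, Tuple[float, float]] = {
    "NaT": (1e-3, 1.0),
    "Kd": (1e-3, 1.0),
    "NaP": (1e-7, 1e-4),
    "KA": (1e-5, 1e-1),
    "CaT": (1e-6, 1e-3),
    "CaL": (1e-6, 1e-2),
    "SK": (1e-6, 1e-2),
    "h": (1e-7, 1e-4),
    "leak": (1e-6, 1e-3),
}


def search_bounds_for(params: ParameterVector) -> ParameterVector:
    """Return a copy of ``params`` with per-channel search bounds applied.

    Parameter names are matched to channels by their stem ("gNaT.s",
    "NaT.u" -> NaT); gamma_Ca/tau_Ca keep their default ranges.  Values
    are clipped into the new bounds.
    """
    stems = {"gNaT": "NaT", "gKd": "Kd", "gNaP": "NaP", "gKA": "KA",
             "pCaT": "CaT", "pCaL": "CaL", "gSK": "SK", "gh": "h",
             "gleak": "leak"}
    lower = params.lower.copy()
    upper = params.upper.copy()
    for i, name in enumerate(params.names):
        stem = name.split(".")[0]
        cid = stems.get(stem, stem)
        if cid in SEARCH_BOUNDS:
            lower[i], upper[i] = SEARCH_BOUNDS[cid]
    values = np.clip(params.values, lower, upper)
    return ParameterVector(list(params.names), values, lower, upper)

# region -> [(channel id, parameter name)]
_DEFAULT_DIST: Dict[str, List[Tuple[str, str]]] = {
    "soma": [
        ("NaT", "gNaT.s"), ("Kd", "gKd.s"), ("NaP", "gNaP.s"), ("KA", "gKA.s"),
        ("CaT", "pCaT.sd"), ("CaL", "pCaL.s"), ("SK", "gSK.s"), ("h", "gh.s"),
        ("leak", "gleak.s"),
    ],
    "dend": [
        ("NaP", "gNaP.d"), ("KA", "gKA.d"), ("CaT", "pCaT.sd"), ("CaL", "pCaL.d"),
        ("SK", "gSK.d"), ("h", "gh.d"), ("leak", "gleak.d"),
    ],
    "axon": [
        ("NaT", "gNaT.a"), ("Kd", "gKd.a"), ("CaT", "pCaT.a"), ("SK", "gSK.a"),
        ("leak", "gleak.a"),
    ],
}


@dataclass
class RegionDistribution:
    """Mapping from morphological region to channel/parameter pairs."""

    regions: Dict[str, List[Tuple[str, str]]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_DIST.items()}
    )

    def __post_init__(self):
        for region in self.regions:
            if region not in ("soma", "dend", "axon"):
                raise ValidationError(f"unknown region {region!r}")
        for region in ("soma", "dend", "axon"):
            chans = [c for c, _ in self.regions.get(region, [])]
            if "leak" not in chans:
                raise ValidationError(f"leak must be present in every region ({region})")
        # CaT shares one parameter between soma and dendrites
        cat_s = dict(self.regions.get("soma", [])).get("CaT")
        cat_d = dict(self.regions.get("dend", [])).get("CaT")
        if cat_s is not None and cat_d is not None and cat_s != cat_d:
            raise ValidationError(
                "CaT must use the same parameter in soma and dendrites"
            )

    def density_parameters(self) -> List[str]:
        seen: List[str] = []
        for region in ("soma", "dend", "axon"):
            for _, pname in self.regions.get(region, []):
                if pname not in seen:
                    seen.append(pname)
        return seen


def default_distribution() -> RegionDistribution:
    return RegionDistribution()


def default_parameter_vector(values: Optional[Mapping[str, float]] = None) -> ParameterVector:
    """The default 22-entry free-parameter vector.

    Missing values default to the lower bound (an effectively passive
    cell); pass a mapping to set ground-truth or optimized values.
    """
    dist = default_distribution()
    names = dist.density_parameters() + ["gamma_Ca", "tau_Ca"]
    lower, upper, vals = [], [], []
    for n in names:
        if n == "gamma_Ca":
            lo, hi = DEFAULT_BOUNDS["gamma_Ca"]
        elif n == "tau_Ca":
            lo, hi = DEFAULT_BOUNDS["tau_Ca"]
        elif n.startswith("p"):
            lo, hi = DEFAULT_BOUNDS["permeability"]
        else:
            lo, hi = DEFAULT_BOUNDS["conductance"]
        lower.append(lo)
        upper.append(hi)
        default = {"gamma_Ca": 0.02, "tau_Ca": 80.0}.get(n, lo)
        vals.append((values or {}).get(n, default))
    return ParameterVector(names, np.array(vals), np.array(lower), np.array(upper))


@dataclass
class CellModel:
    """A morphology + discretization + channels + parameters, ready to run."""

    morphology: Morphology
    graph: CompartmentGraph
    channels: Dict[str, ChannelSpec]
    distribution: RegionDistribution
    params: ParameterVector
    config: SimConfig
    ca_dynamics: CaDynamics = field(default_factory=CaDynamics)

    def density_map(self) -> Dict[Tuple[str, str], float]:
        """(region, channel id) -> density from the parameter vector."""
        out = {}
        pd = self.params.as_dict()
        for region, pairs in self.distribution.regions.items():
            for cid, pname in pairs:
                out[(region, cid)] = pd[pname]
        return out

    def with_params(self, params: ParameterVector) -> "CellModel":
        gamma = params["gamma_Ca"] if "gamma_Ca" in params.names else self.ca_dynamics.gamma
        tau = params["tau_Ca"] if "tau_Ca" in params.names else self.ca_dynamics.tau_decay
        return CellModel(
            self.morphology, self.graph, self.channels, self.distribution,
            params, self.config,
            replace(self.ca_dynamics, gamma=gamma, tau_decay=tau),
        )


def build_cell(
    morph: Morphology,
    dist: Optional[RegionDistribution] = None,
    params: Optional[ParameterVector] = None,
    cfg: Optional[SimConfig] = None,
    channels: Optional[Dict[str, ChannelSpec]] = None,
    expected_count: Optional[int] = 22,
    add_axon_stub: bool = True,
) -> CellModel:
    """Assemble a CellModel, validating parameters against their bounds."""
    dist = dist or default_distribution()
    params = params if params is not None else default_parameter_vector()
    cfg = cfg or SimConfig()
    params.validate(expected_count=expected_count)
    channels = channels or default_channels()
    for region, pairs in dist.regions.items():
        for cid, pname in pairs:
            if cid not in channels:
                raise ValidationError(f"unknown channel {cid!r} in region {region}")
            if pname not in params.names:
                raise ValidationError(f"distribution references unknown parameter {pname!r}")
    if add_axon_stub:
        morph = replace_axon_with_stub(morph)
    graph = discretize(morph, seg_len=cfg.seg_len, ra=cfg.ra)
    gamma = params["gamma_Ca"] if "gamma_Ca" in params.names else 0.02
    tau = params["tau_Ca"] if "tau_Ca" in params.names else 80.0
    return CellModel(
        morphology=morph,
        graph=graph,
        channels=channels,
        distribution=dist,
        params=params,
        config=cfg,
        ca_dynamics=CaDynamics(gamma=gamma, tau_decay=tau),
    )


def single_compartment_reduction(cell: CellModel) -> CellModel:
    """Collapse the cell to one isopotential compartment.

    Total membrane area is preserved and channel densities are
    area-weighted across regions, a faithful surrogate for an
    electrically compact neuron and a fast test vehicle.
    """
    g = cell.graph
    total = g.total_area
    dens = cell.density_map()
    merged: Dict[str, float] = {}
    region_names = {0: "soma", 1: "dend", 2: "axon"}
    region_area = {r: float(np.sum(g.area[g.region == code]))
                   for code, r in region_names.items()}
    for (region, cid), d in dens.items():
        merged[cid] = merged.get(cid, 0.0) + d * region_area.get(region, 0.0) / total

    radius_um = np.sqrt(total / 1e-8 / (4.0 * np.pi))
    from .morphology import Section  # local import to avoid cycle noise

    soma = Section("soma", np.zeros((1, 3)), np.array([2.0 * radius_um]), parent=-1)
    morph = Morphology([soma], name=(cell.morphology.name or "cell") + "_1c")
    graph = discretize(morph, seg_len=cell.config.seg_len, ra=cell.config.ra)
    # one region (soma) carrying the merged densities via a custom layout
    pairs = [(cid, f"{cid}.u") for cid in merged]
    dist = RegionDistribution({"soma": pairs, "dend": [("leak", "gleak.unused")],
                               "axon": [("leak", "gleak.unused")]})
    names = [f"{cid}.u" for cid in merged] + ["gleak.unused", "gamma_Ca", "tau_Ca"]
    values = list(merged.values()) + [1e-7, cell.ca_dynamics.gamma, cell.ca_dynamics.tau_decay]
    lower, upper = [], []
    for cid in merged:
        kind = "permeability" if cid in ("CaT", "CaL") else "conductance"
        lo, hi = DEFAULT_BOUNDS[kind]
        lower.append(lo)
        upper.append(hi)
    lower += [1e-8, DEFAULT_BOUNDS["gamma_Ca"][0], DEFAULT_BOUNDS["tau_Ca"][0]]
    upper += [1e-6, DEFAULT_BOUNDS["gamma_Ca"][1], DEFAULT_BOUNDS["tau_Ca"][1]]
    values_arr = np.clip(np.array(values), np.array(lower), np.array(upper))
    pv = ParameterVector(names, values_arr, np.array(lower), np.array(upper))
    return CellModel(
        morphology=morph,
        graph=graph,
        channels=cell.channels,
        distribution=dist,
        params=pv,
        config=cell.config,
        ca_dynamics=cell.ca_dynamics,
    )
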