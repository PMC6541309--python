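"""Declarative descriptions of membrane current mechanisms.

A :class:`ChannelSpec` holds the kinetics of one Hodgkin-Huxley style
mechanism: a list of gates, a conduction law (ohmic with a reversal
potential, or Goldman-Hodgkin-Katz with a permeability), and a Q10
temperature correction.  The current carried by a channel is

    i = density * sum_t( w_t * prod_g( gate_g ^ e_g ) ) * driving(v)

where most channels have a single term (w=1) of the familiar
``m^x h^y`` shape; the A-type potassium current uses two weighted terms
(fast and slow components).  Gate dynamics follow first-order
relaxation ``n' = (n_inf(v) - n) / tau_n(v)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np

from . import forms

__all__ = ["GateSpec", "ChannelSpec", "CaDynamics", "ChannelState", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a channel definition is internally inconsistent."""


@dataclass
class GateSpec:
    """Kinetics of one activation/inactivation variable.

    ``form`` selects how the steady state and time constant are defined:

    - ``"inf_tau"``: explicit ``inf`` (steady-state) and ``tau`` sub-forms;
    - ``"alpha_beta"``: forward/backward rates, with
      ``n_inf = a/(a+b)`` and ``tau = 1/(a+b)``;
    - ``"calcium_hill"``: calcium-dependent Hill activation
      ``n_inf = cai^h / (cai^h + kd^h)`` with a constant tau
      (voltage independent).

    ``exponent`` is the integer power the gate enters the current law
    with; 0 means the gate is absent from the current.  ``tau_floor``
    [ms] guards against vanishing time constants near singular rate
    expressions.
    """

    name: str
    exponent: int
    form: str
    params: Dict = field(default_factory=dict)
    tau_floor: float = 1e-3

    def __post_init__(self):
        if self.exponent < 0:
            raise ConfigurationError(f"gate {self.name}: exponent must be >= 0")
        if self.tau_floor < 0:
            raise ConfigurationError(f"gate {self.name}: tau_floor must be >= 0")
        if self.form not in ("inf_tau", "alpha_beta", "calcium_hill"):
            raise ConfigurationError(f"gate {self.name}: unknown form {self.form!r}")

    @property
    def is_calcium_dependent(self) -> bool:
        return self.form == "calcium_hill"

    def steady_state(self, v=None, cai=None):
        """Steady-state value in [0, 1] at voltage v [mV] (or [Ca]_i [mM])."""
        if self.form == "inf_tau":
            return np.clip(forms.eval_steady(self.params["inf"], v), 0.0, 1.0)
        if self.form == "alpha_beta":
            a = forms.eval_rate(self.params["alpha"], v)
            b = forms.eval_rate(self.params["beta"], v)
            return np.clip(a / (a + b), 0.0, 1.0)
        # calcium_hill
        cai = np.asarray(cai, dtype=float)
        kd = self.params["kd"]
        h = self.params["hill"]
        c = np.maximum(cai, 1e-12)
        return 1.0 / (1.0 + (kd / c) ** h)

    def time_constant(self, v=None, q10_factor: float = 1.0):
        """Raw time constant [ms] at v, divided by the Q10 rate factor.

        The floor is applied after temperature scaling so that the
        integrator never sees tau <= 0.
        """
        if self.form == "inf_tau":
            tau = forms.eval_tau(self.params["tau"], v)
        elif self.form == "alpha_beta":
            a = forms.eval_rate(self.params["alpha"], v)
            b = forms.eval_rate(self.params["beta"], v)
            tau = 1.0 / (a + b)
        else:  # calcium_hill: voltage-independent constant
            tau = forms.eval_tau(self.params["tau"], 0.0 if v is None else v)
        return np.maximum(tau / q10_factor, self.tau_floor)


@dataclass
class ChannelSpec:
    """One ionic mechanism: gates + conduction law + temperature model."""

    id: str
    ion: str  # Na, K, Ca, nonspecific
    conduction: Dict  # {"law": "ohmic", "erev": mV|"ena"|"ek"} or {"law": "ghk", "z": int, "cao": mM}
    gates: List[GateSpec] = field(default_factory=list)
    q10: float = 1.0
    t_ref: float = 34.0
    # Current-law terms: list of {"weight": w, "gates": {name: exponent}}.
    # Default: single term built from the gates' own exponents.
    terms: Optional[List[Dict]] = None

    def __post_init__(self):
        if self.q10 < 1.0:
            raise ConfigurationError(f"channel {self.id}: q10 must be >= 1")
        law = self.conduction.get("law")
        if law not in ("ohmic", "ghk"):
            raise ConfigurationError(f"channel {self.id}: unknown conduction law {law!r}")
        if self.terms is None:
            self.terms = [
                {
                    "weight": 1.0,
                    "gates": {g.name: g.exponent for g in self.gates if g.exponent > 0},
                }
            ]
        names = {g.name for g in self.gates}
        for term in self.terms:
            for gname in term["gates"]:
                if gname not in names:
                    raise ConfigurationError(
                        f"channel {self.id}: current law references unknown gate {gname!r}"
                    )

    @property
    def is_ghk(self) -> bool:
        return self.conduction["law"] == "ghk"

    def gate(self, name: str) -> GateSpec:
        for g in self.gates:
            if g.name == name:
                return g
        raise ConfigurationError(f"channel {self.id}: no gate named {name!r}")

    def q10_factor(self, temp: float) -> float:
        """Rate speed-up factor q10^((temp - t_ref)/10)."""
        return self.q10 ** ((temp - self.t_ref) / 10.0)

    def resolve_erev(self, e_na: float = 50.0, e_k: float = -90.0) -> float:
        """Reversal potential [mV] with symbolic 'ena'/'ek' resolved."""
        erev = self.conduction.get("erev")
        if erev == "ena":
            return e_na
        if erev == "ek":
            return e_k
        return float(erev)

    def open_fraction(self, state: "ChannelState"):
        """Weighted open probability sum_t w_t * prod_g gate^exp."""
        total = 0.0
        for term in self.terms:
            prod = 1.0
            for gname, expo in term["gates"].items():
                if gname not in state.gates:
                    raise ConfigurationError(
                        f"channel {self.id}: state missing gate {gname!r}"
                    )
                prod = prod * state.gates[gname] ** expo
            total = total + term["weight"] * prod
        return total


@dataclass
class CaDynamics:
    """Single-shell exponential-decay intracellular calcium model.

    d[Ca]/dt = -1e4 * gamma * i_Ca / (2 F depth)  -  ([Ca] - baseline)/tau

    with i_Ca in mA/cm^2, depth in um, concentrations in mM; gamma is the
    fraction of calcium current reaching the shell.
    """

    gamma: float = 0.02
    tau_decay: float = 80.0  # ms
    ca_baseline: float = 5e-5  # mM
    shell_depth: float = 0.1  # um

    def __post_init__(self):
        if not (0.0 < self.gamma <= 1.0):
            raise ConfigurationError("CaDynamics: gamma must be in (0, 1]")
        if self.tau_decay <= 0:
            raise ConfigurationError("CaDynamics: tau_decay must be > 0")


@dataclass
class ChannelState:
    """Instantaneous gate values (clamped to [0,1]) and [Ca]_i [mM]."""

    gates: Dict[str, float] = field(default_factory=dict)
    cai: float = 5e-5

    def __post_init__(self):
        self.gates = {k: float(np.clip(v, 0.0, 1.0)) for k, v in self.gates.items()}
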