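"""Functional forms for gate kinetics.

Channel definition files describe each gate's steady state and time
constant (or forward/backward rates) as a named functional form plus a
small set of real constants.  The evaluator here is the single place
those forms are interpreted, so replacing a channel's constants never
requires code changes.

All forms are vectorized over the voltage argument.
"""
from __future__ import annotations

from typing import Callable, Dict, Mapping

import numpy as np

__all__ = ["eval_rate", "eval_steady", "eval_tau", "RATE_FORMS", "TAU_FORMS"]


def _exp_rate(v, p):
    # A * exp((v - V0) / B)
    return p["A"] * np.exp((v - p["V0"]) / p["B"])


def _sigmoid_rate(v, p):
    # A / (1 + exp(-(v - V0) / B))
    return p["A"] / (1.0 + np.exp(-(v - p["V0"]) / p["B"]))


def _linexp_rate(v, p):
    # A * (v - V0) / (exp((v - V0) / B) - 1), with the analytic limit
    # A * B at v = V0 (l'Hopital).
    x = np.asarray(v, dtype=float) - p["V0"]
    b = p["B"]
    out = np.where(
        np.abs(x) < 1e-9 * abs(b),
        p["A"] * b * np.ones_like(x),
        p["A"] * x / np.expm1(np.where(np.abs(x) < 1e-9 * abs(b), 1.0, x) / b),
    )
    return out


RATE_FORMS: Dict[str, Callable] = {
    "exp": _exp_rate,
    "sigmoid": _sigmoid_rate,
    "linexp": _linexp_rate,
}


def eval_rate(spec: Mapping, v):
    """Evaluate a forward/backward rate expression [1/ms] at voltage v [mV]."""
    try:
        fn = RATE_FORMS[spec["type"]]
    except KeyError as exc:  # pragma: no cover - config error path
        raise KeyError(f"unknown rate form {spec.get('type')!r}") from exc
    return fn(v, spec)


def _boltzmann(v, p):
    # 1 / (1 + exp((v - vhalf) / k)); k < 0 gives an activation curve.
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - p["vhalf"]) / p["k"]))


STEADY_FORMS: Dict[str, Callable] = {
    "boltzmann": _boltzmann,
}


def eval_steady(spec: Mapping, v):
    """Evaluate a steady-state curve (dimensionless, in [0, 1]) at v [mV]."""
    fn = STEADY_FORMS[spec["type"]]
    return fn(v, spec)


def _tau_constant(v, p):
    return p["tau"] * np.ones_like(np.asarray(v, dtype=float))


def _tau_recip2exp(v, p):
    # c + 1 / (exp(a1 + b1*v) + exp(a2 + b2*v))
    v = np.asarray(v, dtype=float)
    return p.get("c", 0.0) + 1.0 / (
        np.exp(p["a1"] + p["b1"] * v) + np.exp(p["a2"] + p["b2"] * v)
    )


def _tau_recip2exp_capped(v, p):
    # recip2exp below vsplit, constant cap above (slow-inactivation forms)
    v = np.asarray(v, dtype=float)
    tau = _tau_recip2exp(v, p)
    return np.where(v < p["vsplit"], tau, p["cap"])


def _tau_piecewise_exp(v, p):
    # v < vsplit: exp((v - V1)/B1);  else: C + exp((v - V2)/B2)
    v = np.asarray(v, dtype=float)
    low = np.exp((v - p["V1"]) / p["B1"])
    high = p["C"] + np.exp((v - p["V2"]) / p["B2"])
    return np.where(v < p["vsplit"], low, high)


TAU_FORMS: Dict[str, Callable] = {
    "constant": _tau_constant,
    "recip2exp": _tau_recip2exp,
    "recip2exp_capped": _tau_recip2exp_capped,
    "piecewise_exp": _tau_piecewise_exp,
}


def eval_tau(spec: Mapping, v):
    """Evaluate a time-constant expression [ms] at voltage v [mV]."""
    fn = TAU_FORMS[spec["type"]]
    return fn(v, spec)
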