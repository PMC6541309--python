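"""Evaluation operations on channel mechanisms.

Sign convention: outward membrane current is positive.  GHK currents
are continuous at v = 0 through the analytic limit of the constant
field expression.
"""
from __future__ import annotations

import numpy as np

from ..constants import FARADAY, GAS_CONSTANT, kelvin
from .spec import CaDynamics, ChannelSpec, ChannelState, ConfigurationError

__all__ = [
    "ghk_flux",
    "eval_current",
    "ih_minf",
    "ih_tau",
    "q10_scale",
    "advance_gate",
    "step_calcium",
]


def ghk_flux(perm, v, cai, cao, z=2, temp=34.0):
    """Goldman-Hodgkin-Katz current density [mA/cm^2].

    Parameters: permeability [cm/s], voltage [mV], inner/outer
    concentrations [mM], ion valence, temperature [degC].  Inward
    current is negative.  At v = 0 the expression is evaluated through
    its series limit ``1e-3 * P z F (cai - cao)``, which makes the
    function continuous there.
    """
    cai = np.asarray(cai, dtype=float)
    cao_arr = np.asarray(cao, dtype=float)
    if np.any(cai < 0) or np.any(cao_arr <= 0):
        raise ValueError("GHK concentrations must be non-negative (cao > 0)")
    v = np.asarray(v, dtype=float)
    T = kelvin(temp)
    # u = z F v / (R T), v in volts
    u = z * FARADAY * (v * 1e-3) / (GAS_CONSTANT * T)
    small = np.abs(u) < 1e-7
    u_safe = np.where(small, 1.0, u)
    # i = 1e-3 * P z F u (cai - cao e^{-u}) / (1 - e^{-u})
    ratio = np.where(
        small,
        cai - cao_arr + 0.5 * u * (cai + cao_arr),  # first-order series in u
        u_safe * (cai - cao_arr * np.exp(-u_safe)) / (-np.expm1(-u_safe)),
    )
    out = 1e-3 * np.asarray(perm, dtype=float) * z * FARADAY * ratio
    if out.ndim == 0:
        return float(out)
    return out


def eval_current(spec: ChannelSpec, density, v, state: ChannelState, temp=34.0,
                 e_na=50.0, e_k=-90.0, cao=2.0):
    """Membrane current density [mA/cm^2] for one channel.

    ``density`` is a conductance [S/cm^2] for ohmic channels or a
    permeability [cm/s] for GHK channels.  Outward positive.
    """
    po = spec.open_fraction(state)
    if spec.is_ghk:
        z = spec.conduction.get("z", 2)
        cao = spec.conduction.get("cao", cao)
        return density * po * ghk_flux(1.0, v, state.cai, cao, z=z, temp=temp)
    erev = spec.resolve_erev(e_na=e_na, e_k=e_k)
    return density * po * (np.asarray(v, dtype=float) - erev)


def ih_minf(v):
    """Steady-state activation of the hyperpolarization-activated current.

    Boltzmann curve with half-activation at -86.4 mV and slope 11.2 mV;
    strictly decreasing in v.
    """
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) + 86.4) / 11.2))


def ih_tau(v):
    """Activation time constant [ms] of the h-current.

    tau(v) = 1 / (exp(-14.59 - 0.086 v) + exp(-1.87 + 0.0701 v));
    positive everywhere with a single interior maximum where the two
    exponential rates are equal.
    """
    v = np.asarray(v, dtype=float)
    return 1.0 / (np.exp(-14.59 - 0.086 * v) + np.exp(-1.87 + 0.0701 * v))


def q10_scale(tau, temp, t_ref, q10):
    """Temperature-scaled time constant: tau / q10^((temp - t_ref)/10)."""
    if q10 < 1.0:
        raise ValueError("q10 must be >= 1")
    return tau / q10 ** ((temp - t_ref) / 10.0)


def advance_gate(gate, n, v, cai=None, dt=0.025, temp=34.0, q10=1.0, t_ref=34.0):
    """Advance one gate by dt [ms] with the exact exponential update.

    For fixed v the relaxation ODE has the closed-form solution
    ``n_inf + (n - n_inf) exp(-dt/tau)``; the result is clamped to [0,1].
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    factor = q10 ** ((temp - t_ref) / 10.0)
    if gate.is_calcium_dependent:
        ninf = gate.steady_state(cai=cai)
    else:
        ninf = gate.steady_state(v=v)
    tau = gate.time_constant(v=v, q10_factor=factor)
    out = ninf + (np.asarray(n, dtype=float) - ninf) * np.exp(-dt / tau)
    return np.clip(out, 0.0, 1.0)


def step_calcium(dyn: CaDynamics, cai, i_ca_total, dt):
    """Advance [Ca]_i by dt [ms] under calcium current i_ca [mA/cm^2].

    The linear ODE  cai' = A - (cai - baseline)/tau  with constant
    source A = -1e4 gamma i_ca / (2 F depth) has fixed point
    baseline + A tau; the step uses the exact exponential relaxation
    toward it.  Outward (positive) calcium current can never drive the
    concentration below baseline.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    source = -1e4 * dyn.gamma * np.asarray(i_ca_total, dtype=float) / (
        2.0 * FARADAY * dyn.shell_depth
    )
    # Outward calcium current cannot pump the shell below baseline
    # (influx-only drive, as in standard exponential-decay mechanisms).
    source = np.maximum(source, 0.0)
    target = dyn.ca_baseline + source * dyn.tau_decay
    out = target + (np.asarray(cai, dtype=float) - target) * np.exp(-dt / dyn.tau_decay)
    return np.maximum(out, 0.0) if np.ndim(out) else max(float(out), 0.0)
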