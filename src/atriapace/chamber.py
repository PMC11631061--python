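"""Chamber constitutive law and activation waveform.

Each cardiac chamber follows an activation-weighted elastance law

    p(V, a) = a * c * E_act * (V - V0) + P_ref * (exp(k * (V/V0 - 1)) - 1)

where ``a`` in [0, 1] is the periodic activation level, the first term the
active (contractile) pressure and the second the passive exponential
filling curve.  Below V0 the passive term is a mild suction, above V0 the
law is monotone increasing in V.  Public timing arguments are in ms.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ParameterError, StateError

__all__ = ["ChamberParams", "activation", "chamber_pressure", "valve_flow"]


@dataclass(frozen=True)
class ChamberParams:
    """Parameters of one chamber.

    Volumes in mL, elastances in mmHg/mL, pressures in mmHg, times in ms.
    ``contractility_scale`` c multiplies the active elastance (1.0 = normal);
    ``relaxation_tau`` is the exponential decay constant of the activation
    tail after the contraction plateau of length ``activation_duration``.
    """

    unstressed_volume: float
    active_elastance: float
    contractility_scale: float
    passive_ref_pressure: float
    passive_stiffness_exponent: float
    activation_onset: float
    activation_duration: float
    relaxation_tau: float

    def __post_init__(self):
        if self.unstressed_volume <= 0:
            raise ParameterError("unstressed_volume must be > 0")
        if self.active_elastance < 0:
            raise ParameterError("active_elastance must be >= 0")
        if not 0 <= self.contractility_scale <= 1.5:
            raise ParameterError("contractility_scale must lie in [0, 1.5]")
        if self.passive_ref_pressure <= 0:
            raise ParameterError("passive_ref_pressure must be > 0")
        if self.passive_stiffness_exponent <= 0:
            raise ParameterError("passive_stiffness_exponent must be > 0")
        if self.activation_duration <= 0 or self.relaxation_tau <= 0:
            raise ParameterError("activation_duration and relaxation_tau must be > 0")

    def scaled(self, **kw) -> "ChamberParams":
        """Return a copy with fields replaced."""
        return replace(self, **kw)


def activation(t_since_onset, d_act: float, tau: float):
    """Activation level in [0, 1] at ``t_since_onset`` ms after onset.

    Rises as sin^2 to its single maximum (1) at ``d_act`` and decays with
    time constant ``tau`` afterwards; 0 for t <= 0.  Accepts scalars or
    arrays.
    """
    if not (np.isfinite(d_act) and np.isfinite(tau)):
        raise ParameterError("d_act and tau must be finite")
    if d_act <= 0 or tau <= 0:
        raise ParameterError("d_act and tau must be > 0")
    t = np.asarray(t_since_onset, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ParameterError("t_since_onset must be finite")
    rise = np.sin(0.5 * np.pi * np.clip(t, 0.0, d_act) / d_act) ** 2
    tail = np.exp(-np.clip(t - d_act, 0.0, None) / tau)
    out = np.where(t <= 0, 0.0, np.where(t <= d_act, rise, tail))
    if out.ndim == 0:
        return float(out)
    return out


def chamber_pressure(params: ChamberParams, volume, activation_level,
                     pericardial_pressure: float = 0.0):
    """Chamber pressure (mmHg) at the given volume and activation level."""
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise StateError("chamber volume must be >= 0")
    a = np.asarray(activation_level, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ParameterError("activation level must lie in [0, 1]")
    x = params.passive_stiffness_exponent * (v / params.unstressed_volume - 1.0)
    passive = params.passive_ref_pressure * np.expm1(np.minimum(x, 40.0))
    active = a * params.contractility_scale * params.active_elastance * (
        v - params.unstressed_volume)
    out = active + passive + pericardial_pressure
    if out.ndim == 0:
        return float(out)
    return out


def valve_flow(p_upstream: float, p_downstream: float, resistance: float,
               inertance: float = 0.0, flow: float = 0.0):
    """Ideal-diode valve flow.

    Without inertance returns the instantaneous flow ``max(dp, 0)/R`` (mL/s).
    With inertance the flow is a state; returns ``(flow, dflow_dt)`` where the
    derivative follows ``L dq/dt = dp - R q`` and is clamped so a closed valve
    (q <= 0 with adverse gradient) stays closed.  Total function: never raises
    for finite pressures.
    """
    dp = p_upstream - p_downstream
    if inertance <= 0.0:
        return dp / resistance if dp > 0.0 else 0.0
    q = max(flow, 0.0)
    dq = (dp - resistance * q) / inertance
    if q <= 0.0 and dq < 0.0:
        dq = 0.0
    return q, dq


def rate_adapted_duration(d_ref_ms: float, cycle_length_ms: float,
                          cl_ref_ms: float, exponent: float = 0.5) -> float:
    """Bazett-like scaling of twitch duration with cycle length.

    Keeps systole a physiologic fraction of the shortening cycle; at the
    reference cycle length the duration equals ``d_ref_ms`` exactly.
    """
    return d_ref_ms * (cycle_length_ms / cl_ref_ms) ** exponent
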