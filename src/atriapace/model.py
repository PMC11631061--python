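"""Closed-loop lumped-parameter model of the heart and circulation.

Eight volume compartments (LA, LV, RA, RV, systemic arteries/veins,
pulmonary arteries/veins) connected by four ideal valves (the mitral valve
carries inertance so early (E) and atrial (A) filling waves separate) and
four vascular resistances.  Chambers follow the activation-weighted
elastance law of :mod:`atriapace.chamber`; a shared exponential pericardial
pressure acting on total heart volume couples the four chambers.

Pacing timing: atrial activation onset defines time zero of each cycle;
ventricular onset follows ``pr_interval`` later, both wrapping modulo the
cycle length (necessary at fast rates where the PR interval exceeds
diastole).  Twitch durations shorten with rate (Bazett-like sqrt scaling).

The virtual HFpEF phenotype is imposed through :class:`PhenotypeConfig`
scalers on a normal reference parameterization: increased LV passive
stiffness, slowed LV relaxation, increased LV wall mass, atrial dilation,
and optionally reduced atrial contractility (atrial myopathy).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import _core
from .chamber import ChamberParams, rate_adapted_duration
from .exceptions import IntegrationError, ParameterError, StateError
from .metrics import BeatMetrics, beat_metrics, cycle_frame

__all__ = [
    "ActivationTiming", "CirculationParams", "PhenotypeConfig", "ModelState",
    "ClosedLoopModel", "SimulationResult",
    "normal_chambers", "default_circulation",
]

COMPARTMENTS = ("la", "lv", "ra", "rv", "sa", "sv", "pa", "pv")

# reference cycle length for rate adaptation of twitch durations (54 bpm)
CL_REF_MS = 60000.0 / 54.0


@dataclass(frozen=True)
class ActivationTiming:
    """Pacing timing: heart rate [bpm] and atrial-to-ventricular delay [ms]."""

    heart_rate: float
    pr_interval: float
    mode: str = "intrinsic"  # "intrinsic" | "av_sequential"

    def __post_init__(self):
        if not 30 <= self.heart_rate <= 250:
            raise ParameterError("heart_rate must lie in [30, 250] bpm")
        if not 0 <= self.pr_interval <= 400:
            raise ParameterError("pr_interval must lie in [0, 400] ms")
        if self.mode not in ("intrinsic", "av_sequential"):
            raise ParameterError("mode must be 'intrinsic' or 'av_sequential'")

    @property
    def cycle_length(self) -> float:
        """Cycle length in ms, 60000 / heart_rate."""
        return 60000.0 / self.heart_rate


@dataclass(frozen=True)
class CirculationParams:
    """Vascular compartments, valves, and the two regulation-adjustable knobs.

    Compliances in mL/mmHg, resistances in mmHg·s/mL, inertance in
    mmHg·s²/mL, volumes in mL.  Valves are ideal diodes (no regurgitant
    leak); only the mitral valve carries inertance by default.
    """

    c_sa: float = 1.4
    v0_sa: float = 600.0
    c_sv: float = 60.0
    v0_sv: float = 2400.0
    c_pa: float = 5.0
    v0_pa: float = 100.0
    c_pv: float = 12.0
    v0_pv: float = 120.0
    r_mitral: float = 0.004
    l_mitral: float = 3.0e-4
    r_aortic: float = 0.005
    r_tricuspid: float = 0.004
    r_pulmonic: float = 0.005
    r_sys: float = 1.05
    r_ven: float = 0.03
    r_pul: float = 0.07
    r_pvn: float = 0.015
    total_blood_volume: float = 4300.0

    def __post_init__(self):
        for name in ("c_sa", "c_sv", "c_pa", "c_pv", "r_mitral", "l_mitral",
                     "r_aortic", "r_tricuspid", "r_pulmonic", "r_sys",
                     "r_ven", "r_pul", "r_pvn"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.total_blood_volume <= (self.v0_sa + self.v0_sv
                                       + self.v0_pa + self.v0_pv):
            raise ParameterError(
                "total_blood_volume must exceed the summed vascular "
                "unstressed volumes")

    def replace(self, **kw) -> "CirculationParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PhenotypeConfig:
    """HFpEF and atrial-myopathy scalers plus baseline pacing timing.

    All scales multiply the normal reference chamber parameters:
    ``lv_passive_stiffness_scale`` the LV passive reference pressure,
    ``lv_relaxation_tau_scale`` the LV relaxation time constant,
    ``lv_mass_scale`` the LV active elastance and passive reference pressure
    jointly (wall-mass effect), ``la_dilation_scale`` the atrial unstressed
    volumes, and ``atrial_contractility_fraction`` the atrial contractility
    (1.0 normal, 0.5 myopathic).
    """

    lv_passive_stiffness_scale: float = 1.0
    lv_relaxation_tau_scale: float = 1.0
    lv_mass_scale: float = 1.0
    la_dilation_scale: float = 1.0
    atrial_contractility_fraction: float = 1.0
    pericardial_constraint_enabled: bool = True
    timing: ActivationTiming = field(
        default_factory=lambda: ActivationTiming(54.0, 153.0))

    def __post_init__(self):
        for name in ("lv_passive_stiffness_scale", "lv_relaxation_tau_scale",
                     "lv_mass_scale", "la_dilation_scale"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0 < self.atrial_contractility_fraction <= 1:
            raise ParameterError(
                "atrial_contractility_fraction must lie in (0, 1]")

    def replace(self, **kw) -> "PhenotypeConfig":
        return replace(self, **kw)


@dataclass
class ModelState:
    """Instantaneous state: 8 compartment volumes [mL], mitral flow [mL/s],
    and time within the cycle [ms]."""

    volumes: np.ndarray
    mitral_flow: float = 0.0
    time_in_cycle: float = 0.0

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.shape != (8,):
            raise StateError("volumes must have shape (8,)")
        if np.any(self.volumes < 0):
            raise StateError("all compartment volumes must be >= 0")

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([self.volumes, [self.mitral_flow]])


def normal_chambers() -> dict:
    """Normal reference chamber parameterization (before phenotype scalers).

    Onset/duration fields here are references at the 54 bpm cycle length;
    the model applies pacing timing and rate adaptation when packing.
    """
    return {
        "la": ChamberParams(35.0, 0.70, 1.0, 0.50, 3.0, 0.0, 100.0, 50.0),
        "lv": ChamberParams(40.0, 4.50, 1.0, 0.08, 1.6, 0.0, 300.0, 40.0),
        "ra": ChamberParams(35.0, 0.55, 1.0, 0.40, 3.0, 0.0, 100.0, 50.0),
        "rv": ChamberParams(40.0, 1.20, 1.0, 0.05, 1.6, 0.0, 300.0, 40.0),
    }


def default_circulation() -> CirculationParams:
    return CirculationParams()


# pericardial constraint (shared exponential on total heart volume)
PERI_P_REF = 0.4
PERI_K = 5.0
PERI_V0 = 580.0


class ClosedLoopModel:
    """The closed-loop model bound to a phenotype, circulation, and timing.

    Parameters
    ----------
    phenotype : PhenotypeConfig
    circulation : CirculationParams, optional
    chambers : dict, optional
        Normal reference chamber parameters keyed "la","lv","ra","rv";
        phenotype scalers are applied on top.
    dt_ms : float
        Fixed integration/output step (default 1 ms).
    valves_open : bool
        Lock all valves open (bidirectional resistive); used with
        ``active=False`` for the static-equilibrium oracle mode.
    active : bool
        If False, zero all active elastances (pure RC network).
    """

    def __init__(self, phenotype: PhenotypeConfig,
                 circulation: Optional[CirculationParams] = None,
                 chambers: Optional[dict] = None,
                 dt_ms: float = 1.0,
                 valves_open: bool = False,
                 active: bool = True):
        self.phenotype = phenotype
        self.circulation = circulation or default_circulation()
        self.dt_ms = float(dt_ms)
        self.valves_open = valves_open
        self.active = active
        base = chambers or normal_chambers()
        self.chambers = self._apply_phenotype(base, phenotype)

    @staticmethod
    def _apply_phenotype(base: dict, ph: PhenotypeConfig) -> dict:
        la, lv, ra, rv = base["la"], base["lv"], base["ra"], base["rv"]
        lv = lv.scaled(
            passive_ref_pressure=(lv.passive_ref_pressure
                                  * ph.lv_passive_stiffness_scale
                                  * ph.lv_mass_scale),
            active_elastance=lv.active_elastance * ph.lv_mass_scale,
            relaxation_tau=lv.relaxation_tau * ph.lv_relaxation_tau_scale,
        )
        la = la.scaled(
            unstressed_volume=la.unstressed_volume * ph.la_dilation_scale,
            contractility_scale=(la.contractility_scale
                                 * ph.atrial_contractility_fraction),
        )
        ra = ra.scaled(
            unstressed_volume=ra.unstressed_volume * ph.la_dilation_scale,
            contractility_scale=(ra.contractility_scale
                                 * ph.atrial_contractility_fraction),
        )
        return {"la": la, "lv": lv, "ra": ra, "rv": rv}

    # ------------------------------------------------------------------
    def with_timing(self, timing: ActivationTiming) -> "ClosedLoopModel":
        m = ClosedLoopModel(self.phenotype.replace(timing=timing),
                            self.circulation, dt_ms=self.dt_ms,
                            valves_open=self.valves_open, active=self.active)
        return m

    def pack(self) -> np.ndarray:
        """Pack parameters into the kernel vector (units: s, mL, mmHg)."""
        ph = self.phenotype
        timing = ph.timing
        cl_ms = timing.cycle_length
        p = np.zeros(_core.NP)
        onsets = {"la": 0.0, "lv": timing.pr_interval % cl_ms,
                  "ra": 0.0, "rv": timing.pr_interval % cl_ms}
        dur_exp = {"la": 0.3, "lv": 0.5, "ra": 0.3, "rv": 0.5}
        for i, name in enumerate(("la", "lv", "ra", "rv")):
            ch = self.chambers[name]
            b = 7 * i
            p[b] = ch.unstressed_volume
            p[b + 1] = (ch.contractility_scale * ch.active_elastance
                        if self.active else 0.0)
            p[b + 2] = ch.passive_ref_pressure
            p[b + 3] = ch.passive_stiffness_exponent
            p[b + 4] = onsets[name] / 1000.0
            d_eff = rate_adapted_duration(ch.activation_duration, cl_ms,
                                          CL_REF_MS, dur_exp[name])
            p[b + 5] = d_eff / 1000.0
            p[b + 6] = ch.relaxation_tau / 1000.0
        c = self.circulation
        p[28:36] = [c.c_sa, c.v0_sa, c.c_sv, c.v0_sv,
                    c.c_pa, c.v0_pa, c.c_pv, c.v0_pv]
        p[36:45] = [c.r_mitral, c.l_mitral, c.r_aortic, c.r_tricuspid,
                    c.r_pulmonic, c.r_sys, c.r_ven, c.r_pul, c.r_pvn]
        p[45:49] = [PERI_P_REF, PERI_K, PERI_V0,
                    1.0 if ph.pericardial_constraint_enabled else 0.0]
        p[49] = cl_ms / 1000.0
        p[50] = 1.0 if self.valves_open else 0.0
        return p

    def initial_state(self) -> ModelState:
        """A plausible volume distribution of the total blood volume."""
        c = self.circulation
        vh = {"la": 1.6, "lv": 2.2, "ra": 1.6, "rv": 2.2}  # x unstressed
        vols = np.array([self.chambers[n].unstressed_volume * vh[n]
                         for n in ("la", "lv", "ra", "rv")])
        rest = c.total_blood_volume - vols.sum()
        if rest <= 0:
            raise StateError("total blood volume below heart volumes")
        # distribute the remainder over the vessels at a common pressure
        caps = np.array([c.c_sa, c.c_sv, c.c_pa, c.c_pv])
        v0s = np.array([c.v0_sa, c.v0_sv, c.v0_pa, c.v0_pv])
        stressed = rest - v0s.sum()
        if stressed <= 0:
            raise StateError("total blood volume below vascular unstressed "
                             "volumes")
        press = stressed / caps.sum()
        vves = v0s + caps * press
        # bias arterial compartment toward a physiologic starting pressure
        shift = min(c.c_sa * 70.0, vves[1] - c.v0_sv)
        vves[0] += shift
        vves[1] -= shift
        return ModelState(np.concatenate([vols, vves]))

    # ------------------------------------------------------------------
    def run_cycle(self, y: np.ndarray):
        """One cycle from state vector ``y``; returns (Y, AUX, y_end)."""
        p = self.pack()
        Y, AUX, ok = _core.integrate_cycle(np.asarray(y, dtype=float), p,
                                           self.dt_ms / 1000.0)
        if not ok:
            raise StateError("compartment volume became negative during "
                             "integration")
        if not np.all(np.isfinite(Y)):
            raise IntegrationError("non-finite state encountered",
                                   {"last_state": Y[-1]})
        return Y, AUX, Y[-1].copy()

    def simulate(self, n_beats: Optional[int] = None,
                 until_steady: bool = True,
                 steady_tol: float = 1e-3,
                 max_beats: int = 200,
                 initial: Optional[ModelState] = None) -> "SimulationResult":
        """Run beats until periodic steady state (or ``n_beats``).

        Steady state is declared when the state vector at consecutive beat
        onsets differs by less than ``steady_tol`` in max relative norm.
        """
        if n_beats is not None:
            until_steady = False
        state = initial or self.initial_state()
        y = state.y
        onset_states = [y.copy()]
        steady = False
        beats = 0
        limit = n_beats if n_beats is not None else max_beats
        Y = AUX = None
        while beats < limit:
            Y, AUX, y_end = self.run_cycle(y)
            beats += 1
            prev = y
            y = y_end
            onset_states.append(y.copy())
            if until_steady:
                scale = np.maximum(np.abs(prev), 1e-9)
                rel = np.max(np.abs(y[:8] - prev[:8]) / scale[:8])
                if rel < steady_tol:
                    steady = True
                    break
        if Y is None:
            raise IntegrationError("no beats were simulated")
        if until_steady and not steady:
            warnings.warn("steady state not reached within "
                          f"{max_beats} beats", stacklevel=2)
        frame = cycle_frame(Y, AUX, self.dt_ms)
        metrics = beat_metrics(
            frame, heart_rate=self.phenotype.timing.heart_rate,
            pr_interval_ms=self.phenotype.timing.pr_interval %
            self.phenotype.timing.cycle_length)
        return SimulationResult(model=self, trajectory=frame,
                                metrics=metrics, steady=steady,
                                n_beats=beats,
                                onset_states=np.asarray(onset_states))


@dataclass
class SimulationResult:
    """Beat-resolved output of one simulation.

    ``trajectory`` is the last simulated cycle on the 1-ms grid (time_ms,
    8 volumes, chamber/vessel pressures, valve and peripheral flows);
    ``metrics`` the per-beat haemodynamic summary of that cycle.
    """

    model: ClosedLoopModel
    trajectory: pd.DataFrame
    metrics: BeatMetrics
    steady: bool
    n_beats: int
    onset_states: np.ndarray

    def summary(self) -> str:
        m = self.metrics
        t = self.model.phenotype.timing
        lines = [
            "Closed-loop simulation summary",
            "------------------------------",
            f"heart rate        {t.heart_rate:8.1f} bpm",
            f"PR interval       {t.pr_interval:8.0f} ms",
            f"beats simulated   {self.n_beats:8d}  (steady={self.steady})",
            f"mLAP              {m.mlap:8.2f} mmHg",
            f"peak LAP          {m.peak_lap:8.2f} mmHg",
            f"LVEDP             {m.lvedp:8.2f} mmHg",
            f"LVEDV             {m.lvedv:8.1f} mL",
            f"SV                {m.sv:8.1f} mL",
            f"CO                {m.co:8.2f} L/min",
            f"MAP               {m.map:8.1f} mmHg",
            f"LAV max           {m.lav_max:8.1f} mL",
            f"E/A ratio         {m.ea_ratio:8.2f}"
            + ("  (fused)" if m.ea_fused else ""),
        ]
        return "\n".join(lines)
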