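"""Homeostatic pressure-flow regulation.

After each steady-ish beat (the loop first lets the transient of the
previous adjustment die down), systemic resistance and total blood volume
are nudged multiplicatively until beat-averaged systemic flow and mean
arterial pressure sit on their set-points (5.0 L/min and 92 mmHg by
default), independent of pacing settings:

    R_sys <- R_sys * [(MAP*/CO*) / (MAP/CO)]^0.5
    V_tot <- V_tot * (MAP*/MAP)^0.125

Both updates are scale-free, monotone negative feedback, and exactly the
identity at the set-points.  Volume added or removed enters through the
systemic venous compartment (the most compliant reservoir).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ParameterError, RegulationError
from .model import ClosedLoopModel, CirculationParams, ModelState

__all__ = ["RegulationTargets", "RegulationResult", "regulate"]


@dataclass(frozen=True)
class RegulationTargets:
    """Set-points and convergence policy of the regulation loop."""

    co_target: float = 5.0         # L/min
    map_target: float = 92.0       # mmHg
    rel_tolerance: float = 0.005
    consecutive_beats_required: int = 3
    max_beats: int = 500

    def __post_init__(self):
        if self.co_target <= 0 or self.map_target <= 0:
            raise ParameterError("targets must be > 0")
        if not 0 < self.rel_tolerance < 0.05:
            raise ParameterError("rel_tolerance must lie in (0, 0.05)")
        if self.consecutive_beats_required < 1 or self.max_beats < 1:
            raise ParameterError("beat counts must be >= 1")


def update_parameters(r_sys: float, v_tot: float, co: float, map_: float,
                      targets: RegulationTargets, gain: float = 0.5,
                      volume_gain: float = 0.125):
    """One multiplicative regulation update; identity when on target.

    The resistance moves the measured systemic vascular resistance MAP/CO
    toward the target ratio (negative feedback), the volume moves MAP toward
    its set-point through preload.  The volume gain is smaller because MAP
    answers a volume change only after several beats of venous transport;
    equal gains produce a limit cycle.  Per-beat factors are clipped for
    robustness far from the set-points; near them the clips are inactive and
    the fixed point is exact.
    """
    ratio = (map_ / co) / (targets.map_target / targets.co_target)
    fr = min(max(ratio ** -gain, 0.7), 1.4)
    fv = min(max((targets.map_target / map_) ** volume_gain, 0.95), 1.05)
    return r_sys * fr, v_tot * fv


@dataclass
class RegulationResult:
    """Converged (or last) circulation parameters plus the beat log."""

    circulation: CirculationParams
    converged: bool
    log: pd.DataFrame
    state: ModelState
    targets: RegulationTargets = field(default_factory=RegulationTargets)

    @property
    def n_beats(self) -> int:
        return len(self.log)

    def summary(self) -> str:
        last = self.log.iloc[-1]
        return (
            "Pressure-flow regulation\n"
            "------------------------\n"
            f"converged        {self.converged} ({self.n_beats} beats)\n"
            f"CO               {last['co']:.3f} L/min "
            f"(target {self.targets.co_target})\n"
            f"MAP              {last['map']:.2f} mmHg "
            f"(target {self.targets.map_target})\n"
            f"R_sys            {self.circulation.r_sys:.4f} mmHg·s/mL\n"
            f"V_tot            {self.circulation.total_blood_volume:.0f} mL"
        )


def regulate(model: ClosedLoopModel,
             targets: Optional[RegulationTargets] = None,
             initial: Optional[ModelState] = None,
             gain: float = 0.5) -> RegulationResult:
    """Run the regulation loop on ``model`` until both set-points hold.

    Convergence requires both |CO - CO*| and |MAP - MAP*| within the relative
    tolerance for ``consecutive_beats_required`` consecutive beats.  Returns
    the last parameters regardless, with ``converged=False`` when the beat
    cap is exceeded.  Divergence (vanishing MAP or negative volumes) raises
    :class:`RegulationError` carrying the last good state.
    """
    targets = targets or RegulationTargets()
    state = initial or model.initial_state()
    y = state.y.copy()
    rows = []
    streak = 0
    converged = False
    beats = 0
    settle_tol = 1e-3
    settle_cap = 20
    work = ClosedLoopModel(model.phenotype, model.circulation,
                           dt_ms=model.dt_ms, valves_open=model.valves_open,
                           active=model.active)
    while beats < targets.max_beats:
        # let the transient of the previous update die down: parameter
        # changes applied against a still-moving state excite a sustained
        # controller-plant limit cycle
        state_rel = np.inf
        AUX = None
        for _ in range(settle_cap):
            y_prev = y.copy()
            try:
                Y, AUX, y_end = work.run_cycle(y)
            except Exception as exc:
                raise RegulationError(
                    "regulation diverged",
                    {"beat": beats, "last_state": y,
                     "circulation": work.circulation}) from exc
            y = y_end
            beats += 1
            state_rel = float(np.max(np.abs(y[:8] - y_prev[:8])
                                     / np.maximum(np.abs(y_prev[:8]), 1e-9)))
            if state_rel < settle_tol:
                break
        map_ = float(AUX[:-1, 4].mean())
        # CO measured at the pump (beat-averaged aortic flow): measuring at
        # the systemic resistance would make the R_sys update self-referential
        co = float(AUX[:-1, 10].mean()) * 60.0 / 1000.0  # L/min
        circ_now = work.circulation
        rows.append((beats - 1, co, map_, circ_now.r_sys,
                     circ_now.total_blood_volume))
        if map_ <= 1.0 or co <= 0.0:
            raise RegulationError("regulation diverged (MAP or flow "
                                  "collapsed)",
                                  {"beat": beats, "map": map_, "co": co})
        ok = (abs(co - targets.co_target) / targets.co_target
              < targets.rel_tolerance
              and abs(map_ - targets.map_target) / targets.map_target
              < targets.rel_tolerance
              # also quasi-periodic, so the set-points survive settling
              and state_rel < 2e-3)
        streak = streak + 1 if ok else 0
        if streak >= targets.consecutive_beats_required:
            converged = True
            break
        r_new, v_new = update_parameters(
            circ_now.r_sys, circ_now.total_blood_volume, co, map_, targets,
            gain)
        dv = v_new - circ_now.total_blood_volume
        if y[5] + dv <= 0:
            raise RegulationError("regulation diverged (venous volume "
                                  "exhausted)", {"beat": beats})
        y[5] += dv
        work = ClosedLoopModel(
            model.phenotype,
            circ_now.replace(r_sys=r_new, total_blood_volume=v_new),
            dt_ms=model.dt_ms, valves_open=model.valves_open,
            active=model.active)
    log = pd.DataFrame(rows, columns=["beat", "co", "map", "r_sys", "v_tot"])
    return RegulationResult(circulation=work.circulation,
                            converged=converged, log=log,
                            state=ModelState(y[:8], y[8]),
                            targets=targets)
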