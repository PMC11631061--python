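"""Per-beat haemodynamic metrics from a simulated cycle."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = ["BeatMetrics", "beat_metrics", "cycle_frame"]

TRAJ_COLUMNS = [
    "time_ms",
    "v_la", "v_lv", "v_ra", "v_rv", "v_sa", "v_sv", "v_pa", "v_pv",
    "p_la", "p_lv", "p_ra", "p_rv", "p_sa", "p_sv", "p_pa", "p_pv", "p_peri",
    "q_mit", "q_ao", "q_tri", "q_pu", "q_sys", "q_ven", "q_pul", "q_pvn",
]


def cycle_frame(Y: np.ndarray, AUX: np.ndarray, dt_ms: float) -> pd.DataFrame:
    """Assemble the kernel output of one cycle into a tidy DataFrame."""
    n = Y.shape[0]
    t = np.arange(n) * dt_ms
    data = np.column_stack([t, Y[:, :8], AUX[:, :9], AUX[:, 9:17]])
    # replace the integrated mitral state column with the aux one (identical)
    return pd.DataFrame(data, columns=TRAJ_COLUMNS)


@dataclass(frozen=True)
class BeatMetrics:
    """Per-beat haemodynamic summary.

    mLAP is the beat-time-averaged LA pressure (the study's endpoint);
    LVEDV/LVEDP are taken at ventricular activation onset; E and A are the
    early and atrial peaks of the mitral flow wave, ``ea_fused`` is set when
    no interior minimum below 20% of the smaller peak separates them.
    """

    mlap: float
    peak_lap: float
    lvedp: float
    lvedv: float
    sv: float
    co: float
    map: float
    lav_max: float
    e_peak: float
    a_peak: float
    ea_ratio: float
    ea_fused: bool


def _ea_waves(q_mit: np.ndarray, v_onset_idx: int, dt_ms: float):
    """Identify E and A mitral-flow peaks on one periodic beat.

    The beat (which starts at atrial activation onset) is rolled to start at
    ventricular onset so diastole is contiguous: systole first, then the E
    wave, then the A wave riding on the next atrial contraction.
    """
    n = len(q_mit)
    rolled = np.roll(q_mit, -v_onset_idx)
    qmax = rolled.max()
    if qmax <= 0:
        return 0.0, 0.0, np.nan, True
    peaks, _ = find_peaks(rolled, height=0.05 * qmax,
                          distance=max(int(30 / dt_ms), 1))
    # position of atrial onset in the rolled frame
    atrial_pos = (n - v_onset_idx) % n
    if len(peaks) == 0:
        return float(qmax), float(qmax), 1.0, True
    if len(peaks) == 1:
        v = float(rolled[peaks[0]])
        return v, v, 1.0, True
    # A: the latest peak at/after atrial onset (small tolerance for the
    # upstroke starting just before the detected onset sample)
    tol = int(30 / dt_ms)
    a_cands = peaks[peaks >= atrial_pos - tol]
    if len(a_cands) == 0:
        a_idx = peaks[-1]
    else:
        a_idx = a_cands[np.argmax(rolled[a_cands])]
    others = peaks[peaks < a_idx]
    if len(others) == 0:
        v = float(rolled[a_idx])
        return v, v, 1.0, True
    e_idx = others[np.argmax(rolled[others])]
    e_val = float(rolled[e_idx])
    a_val = float(rolled[a_idx])
    interior = rolled[e_idx:a_idx + 1]
    fused = interior.min() > 0.2 * min(e_val, a_val)
    ratio = e_val / a_val if a_val > 0 else np.inf
    return e_val, a_val, float(ratio), bool(fused)


def beat_metrics(trajectory: pd.DataFrame, heart_rate: float,
                 pr_interval_ms: float) -> BeatMetrics:
    """Compute :class:`BeatMetrics` over exactly one cycle of samples.

    The trajectory must span one full cycle starting at atrial activation
    onset, endpoint inclusive.  A non-periodic input (endpoints differing by
    more than 1%) triggers a warning; metrics are still computed.
    """
    t = trajectory["time_ms"].to_numpy()
    dt_ms = t[1] - t[0]
    first = trajectory.iloc[0][["v_la", "v_lv", "v_ra", "v_rv"]].to_numpy()
    last = trajectory.iloc[-1][["v_la", "v_lv", "v_ra", "v_rv"]].to_numpy()
    if np.max(np.abs(last - first) / np.maximum(np.abs(first), 1e-9)) > 0.01:
        warnings.warn("trajectory endpoints differ by more than 1%; "
                      "metrics computed on a non-periodic beat", stacklevel=2)
    # periodic averages exclude the duplicated endpoint
    body = trajectory.iloc[:-1]
    mlap = float(body["p_la"].mean())
    peak_lap = float(trajectory["p_la"].max())
    v_onset = int(round(pr_interval_ms / dt_ms)) % len(body)
    lvedv = float(trajectory["v_lv"].iloc[v_onset])
    lvedp = float(trajectory["p_lv"].iloc[v_onset])
    sv = lvedv - float(trajectory["v_lv"].min())
    co = sv * heart_rate / 1000.0
    map_ = float(body["p_sa"].mean())
    lav_max = float(trajectory["v_la"].max())
    e_peak, a_peak, ea_ratio, ea_fused = _ea_waves(
        body["q_mit"].to_numpy(), v_onset, dt_ms)
    return BeatMetrics(mlap=mlap, peak_lap=peak_lap, lvedp=lvedp,
                       lvedv=lvedv, sv=sv, co=co, map=map_, lav_max=lav_max,
                       e_peak=e_peak, a_peak=a_peak, ea_ratio=ea_ratio,
                       ea_fused=ea_fused)
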