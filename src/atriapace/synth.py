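"""Synthetic clinical-style recordings with exact ground truth.

Emulates the alternating accelerated-pacing protocol: 30-s stretches of
sinus rhythm alternate with 30-s paced stretches whose rate climbs in
10-bpm steps from the nearest decade above the intrinsic rate up to the
Wenckebach rate.  Signal morphology is analytic (Gaussian bumps), so every
atrial and ventricular onset, every segment boundary, and every per-rate
mLAP and PR value is known exactly.  The programmed ground truth follows
the clinically observed shapes: a U-shaped (Gaussian-well) mLAP(rate)
profile with its floor at the optimal rate, linear PR prolongation with
rate, and deterministic 4:1 dropped beats at the Wenckebach rate.  White
noise, 50 Hz interference, and slow baseline drift are added last.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .model import ActivationTiming, ClosedLoopModel
from .protocol import Recording
from .regulation import RegulationTargets, regulate

__all__ = ["SyntheticConfig", "GroundTruth", "generate_recording",
           "generate_cohort", "model_driven_recording", "rate_schedule"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults follow the clinical cohort's medians
    (sinus 55 bpm, sinus mLAP 12.8 mmHg, optimal rate 100 bpm with a
    2.3 mmHg dip, PR 153 ms prolonging ~1.7 ms/bpm, Wenckebach at 140)."""

    seed: int = 0
    sample_rate: float = 1000.0
    sinus_hr: float = 55.0
    segment_s: float = 30.0
    # mLAP(rate) = m_sinus - depth * exp(-((rate - r_opt)/width)^2)
    m_sinus: float = 12.8
    depth: float = 2.3
    r_opt: float = 100.0
    width: float = 25.0
    # PR(rate) = pr0 + slope * (rate - sinus_hr), capped
    pr0: float = 153.0
    pr_slope: float = 1.7
    pr_cap: float = 350.0
    wenckebach_rate: float = 140.0
    drop_k: int = 4                     # every k-th spike drops its QRS
    # noise
    ecg_noise_sd: float = 0.02          # mV
    lap_noise_sd: float = 0.2           # mmHg
    cs_noise_sd: float = 0.01           # mV
    mains_amp_ecg: float = 0.05         # 50 Hz, mV
    mains_amp_lap: float = 0.05         # mmHg
    drift_amp_ecg: float = 0.15         # mV
    drift_amp_lap: float = 0.2          # mmHg
    drift_period_s: float = 40.0
    # ECG morphology (Gaussian bumps; amplitudes mV, widths/offsets ms)
    p_amp: float = 0.15
    p_sigma: float = 15.0
    p_offset: float = 40.0              # P centre after atrial onset
    q_amp: float = -0.12
    q_sigma: float = 5.0
    q_offset: float = 12.0              # Q centre after ventricular onset
    r_amp: float = 1.0
    r_sigma: float = 11.0
    r_offset: float = 32.0
    s_amp: float = -0.2
    s_sigma: float = 6.0
    s_offset: float = 52.0
    t_amp: float = 0.3
    t_sigma: float = 40.0
    # LAP morphology (mmHg)
    a_amp: float = 3.0
    v_amp: float = 2.5
    cannon_amp: float = 6.0
    spike_amp: float = 2.0              # CS pacing-spike amplitude, mV

    def __post_init__(self):
        if self.depth < 0 or self.pr0 <= 0:
            raise ConfigError("depth must be >= 0 and pr0 > 0")
        for f in ("ecg_noise_sd", "lap_noise_sd", "cs_noise_sd",
                  "mains_amp_ecg", "mains_amp_lap", "drift_amp_ecg",
                  "drift_amp_lap"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{f} must be >= 0")
        sched = rate_schedule(self.sinus_hr, self.wenckebach_rate)
        if not sched:
            raise ConfigError("wenckebach_rate is below the first scheduled "
                              "pacing rate")
        if not sched[0] <= self.r_opt <= sched[-1]:
            raise ConfigError("r_opt must lie within the rate schedule")

    def replace(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)

    def mlap_profile(self, rate: float) -> float:
        return self.m_sinus - self.depth * np.exp(
            -((rate - self.r_opt) / self.width) ** 2)

    def pr_profile(self, rate: float) -> float:
        return min(self.pr0 + self.pr_slope * (rate - self.sinus_hr),
                   self.pr_cap)


def rate_schedule(sinus_hr: float, wenckebach_rate: float) -> List[float]:
    """Paced rates: nearest decade above the intrinsic rate, step 10,
    up to and including the Wenckebach rate."""
    start = (int(sinus_hr) // 10 + 1) * 10
    return [float(r) for r in range(start, int(wenckebach_rate) + 1, 10)]


@dataclass
class GroundTruth:
    """Exact bookkeeping of everything the generator emitted."""

    segments: pd.DataFrame       # kind, rate, start, end  (samples)
    beats: pd.DataFrame          # atrial_onset, qrs_onset, paced, dropped,
                                 # rate (NaN qrs_onset for dropped beats)
    mlap_per_rate: dict          # rate -> programmed mLAP (mmHg)
    pr_per_rate: dict            # rate -> programmed PR (ms)
    sinus_mlap: float
    sinus_pr: float
    optimal_rate: float
    max_rate: float


def _gauss(t, centre, sigma):
    return np.exp(-0.5 * ((t - centre) / sigma) ** 2)


def _add_bump(sig, fs, centre_s, sigma_ms, amp):
    sigma = sigma_ms / 1000.0
    lo = max(int((centre_s - 5 * sigma) * fs), 0)
    hi = min(int((centre_s + 5 * sigma) * fs) + 1, len(sig))
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    sig[lo:hi] += amp * _gauss(t, centre_s, sigma * 1000.0 / 1000.0)


def _beat_times(start_s: float, end_s: float, cl_s: float) -> np.ndarray:
    n = int(np.floor((end_s - start_s) / cl_s + 1e-9))
    return start_s + np.arange(n) * cl_s


def generate_recording(config: SyntheticConfig
                       ) -> Tuple[Recording, GroundTruth]:
    """Synthesize one full-protocol recording plus its ground truth."""
    cfg = config
    fs = cfg.sample_rate
    rng = np.random.default_rng(cfg.seed)
    rates = rate_schedule(cfg.sinus_hr, cfg.wenckebach_rate)

    plan = [("sinus", None)]
    for r in rates:
        plan.append(("paced", r))
        plan.append(("sinus", None))
    n_total = int(round(len(plan) * cfg.segment_s * fs))
    t_total = n_total / fs

    ecg = np.zeros(n_total)
    lap = np.zeros(n_total)
    cs = np.zeros(n_total)

    seg_rows = []
    beat_rows = []
    paced_idx = 0
    for si, (kind, rate) in enumerate(plan):
        t0 = si * cfg.segment_s
        t1 = t0 + cfg.segment_s
        seg_rows.append({"kind": kind, "rate": rate,
                         "start": int(round(t0 * fs)),
                         "end": int(round(t1 * fs))})
        hr = cfg.sinus_hr if kind == "sinus" else rate
        cl = 60.0 / hr
        pr_ms = cfg.pr0 if kind == "sinus" else cfg.pr_profile(rate)
        pr_s = pr_ms / 1000.0
        level = (cfg.m_sinus if kind == "sinus" else cfg.mlap_profile(rate))
        wenck = kind == "paced" and rate >= cfg.wenckebach_rate
        onsets = _beat_times(t0, t1, cl)
        lap_seg = np.zeros(n_total)  # bumps only; mean-adjusted per cycle
        for bi, ta in enumerate(onsets):
            dropped = bool(wenck and (bi % cfg.drop_k == cfg.drop_k - 1))
            tv = ta + pr_s
            beat_rows.append({
                "atrial_onset": int(round(ta * fs)),
                "qrs_onset": np.nan if dropped else int(round(tv * fs)),
                "paced": kind == "paced", "dropped": dropped,
                "rate": rate if kind == "paced" else np.nan})
            # --- ECG ---
            if kind == "sinus":
                _add_bump(ecg, fs, ta + cfg.p_offset / 1000.0, cfg.p_sigma,
                          cfg.p_amp)
            else:
                s0 = int(round(ta * fs))
                w = max(int(round(0.001 * fs)), 1)
                if s0 + 2 * w <= n_total:
                    cs[s0:s0 + w] += cfg.spike_amp
                    cs[s0 + w:s0 + 2 * w] -= cfg.spike_amp
            if not dropped:
                for amp, sig, off in ((cfg.q_amp, cfg.q_sigma, cfg.q_offset),
                                      (cfg.r_amp, cfg.r_sigma, cfg.r_offset),
                                      (cfg.s_amp, cfg.s_sigma,
                                       cfg.s_offset)):
                    _add_bump(ecg, fs, tv + off / 1000.0, sig, amp)
                t_centre = tv + 0.10 + 0.18 * cl
                _add_bump(ecg, fs, t_centre, cfg.t_sigma, cfg.t_amp)
                _add_bump(cs, fs, tv + cfg.r_offset / 1000.0,
                          cfg.r_sigma, 0.1 * cfg.r_amp)
            # --- LAP bumps ---
            cannon = (not dropped) and pr_s >= 0.5 * cl
            if cannon:
                # atrial systole lands on early diastole of the previous
                # beat: a-wave fuses with the v-wave at high amplitude
                _add_bump(lap_seg, fs, ta + 0.08, 60.0,
                          cfg.cannon_amp)
            else:
                _add_bump(lap_seg, fs, ta + 0.08, 50.0, cfg.a_amp)
            if not dropped:
                _add_bump(lap_seg, fs, tv + 0.35 * min(cl / 1.0, 1.0),
                          90.0, cfg.v_amp)
        # zero-mean the bumps per cycle so the programmed level IS the mLAP
        for ta in onsets:
            a = int(round(ta * fs))
            b = min(int(round((ta + cl) * fs)), n_total)
            if b > a:
                lap_seg[a:b] -= lap_seg[a:b].mean()
        s0, s1 = int(round(t0 * fs)), min(int(round(t1 * fs)), n_total)
        lap[s0:s1] += level + lap_seg[s0:s1]
        if kind == "paced":
            paced_idx += 1

    # noise, mains, drift
    t = np.arange(n_total) / fs
    ecg += cfg.mains_amp_ecg * np.sin(2 * np.pi * 50.0 * t
                                      + rng.uniform(0, 2 * np.pi))
    lap += cfg.mains_amp_lap * np.sin(2 * np.pi * 50.0 * t
                                      + rng.uniform(0, 2 * np.pi))
    ecg += cfg.drift_amp_ecg * np.sin(2 * np.pi * t / cfg.drift_period_s
                                      + rng.uniform(0, 2 * np.pi))
    lap += cfg.drift_amp_lap * np.sin(2 * np.pi * t / cfg.drift_period_s
                                      + rng.uniform(0, 2 * np.pi))
    ecg += rng.normal(0, cfg.ecg_noise_sd, n_total)
    lap += rng.normal(0, cfg.lap_noise_sd, n_total)
    cs += rng.normal(0, cfg.cs_noise_sd, n_total)

    rec = Recording(sample_rate=fs, ecg=ecg, lap=lap, cs=cs,
                    patient_id=f"synth-{cfg.seed}")
    non_w = [r for r in rates if r < cfg.wenckebach_rate]
    mlap = {r: float(cfg.mlap_profile(r)) for r in rates}
    opt_pool = non_w if non_w else rates
    optimal = min(opt_pool, key=lambda r: mlap[r])
    truth = GroundTruth(
        segments=pd.DataFrame(seg_rows),
        beats=pd.DataFrame(beat_rows),
        mlap_per_rate=mlap,
        pr_per_rate={r: float(cfg.pr_profile(r)) for r in rates},
        sinus_mlap=cfg.m_sinus, sinus_pr=cfg.pr0,
        optimal_rate=float(optimal),
        max_rate=float(max(non_w)) if non_w else float(rates[-1]))
    return rec, truth


@dataclass(frozen=True)
class CohortDispersion:
    """Per-patient SDs around the generator defaults (clinical moments)."""

    sinus_hr_sd: float = 5.0
    m_sinus_sd: float = 4.0
    depth_sd: float = 1.4
    r_opt_sd: float = 20.0
    pr0_sd: float = 20.0
    pr_slope_sd: float = 0.4
    wenckebach_sd: float = 10.0


def generate_cohort(n: int, seed: int = 0,
                    dispersion: Optional[CohortDispersion] = None,
                    base: Optional[SyntheticConfig] = None
                    ) -> Tuple[List[SyntheticConfig], pd.DataFrame]:
    """Draw ``n`` patient configurations and their programmed truth table.

    Recordings are generated lazily (call :func:`generate_recording` on each
    returned config) to keep memory at one recording at a time.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    disp = dispersion or CohortDispersion()
    base = base or SyntheticConfig()
    rng = np.random.default_rng(seed)
    configs, rows = [], []
    for i in range(n):
        sinus = float(np.clip(base.sinus_hr
                              + rng.normal(0, disp.sinus_hr_sd), 40, 75))
        start = (int(sinus) // 10 + 1) * 10
        wb = 10 * round(float(base.wenckebach_rate
                              + rng.normal(0, disp.wenckebach_sd)) / 10)
        wb = float(np.clip(wb, start + 20, 160))
        r_opt = 10 * round(float(base.r_opt
                                 + rng.normal(0, disp.r_opt_sd)) / 10)
        r_opt = float(np.clip(r_opt, start, wb - 10))
        cfg = base.replace(
            # per-patient seeds are offsets so that n=1 with zero dispersion
            # reproduces the base recording exactly
            seed=int((base.seed + i) % (2 ** 31 - 1)),
            sinus_hr=sinus,
            m_sinus=float(np.clip(base.m_sinus
                                  + rng.normal(0, disp.m_sinus_sd), 4, 30)),
            depth=float(np.clip(base.depth + rng.normal(0, disp.depth_sd),
                                0.2, 8.0)),
            r_opt=r_opt,
            pr0=float(np.clip(base.pr0 + rng.normal(0, disp.pr0_sd),
                              90, 220)),
            pr_slope=float(np.clip(base.pr_slope
                                   + rng.normal(0, disp.pr_slope_sd),
                                   0.3, 3.0)),
            wenckebach_rate=wb)
        configs.append(cfg)
        rates = rate_schedule(cfg.sinus_hr, cfg.wenckebach_rate)
        non_w = [r for r in rates if r < cfg.wenckebach_rate]
        mlap = {r: cfg.mlap_profile(r) for r in rates}
        pool = non_w if non_w else rates
        opt = min(pool, key=lambda r: mlap[r])
        rows.append({"patient": i, "sinus_hr": cfg.sinus_hr,
                     "sinus_mlap": cfg.m_sinus,
                     "optimal_rate": float(opt),
                     "mlap_at_optimal": float(mlap[opt]),
                     "dmlap_at_optimal": float(mlap[opt] - cfg.m_sinus),
                     "max_rate": float(max(non_w)) if non_w
                     else float(rates[-1])})
    return configs, pd.DataFrame(rows)


def model_driven_recording(phenotype, schedule_config: SyntheticConfig,
                           regulation: Optional[RegulationTargets] = None,
                           circulation=None, warm_state=None
                           ) -> Tuple[Recording, pd.DataFrame]:
    """Recording whose LA-pressure channel comes from the closed-loop model.

    For every scheduled segment the calibrated model is regulated at that
    (rate, PR) and its steady-beat LA pressure trace is tiled across the
    30-s stretch; ECG and CS channels are synthesized from the same timing.
    Returns the recording and a per-segment truth table of model
    BeatMetrics.  Non-converged segments are skipped and flagged.
    """
    cfg = schedule_config
    fs = cfg.sample_rate
    regulation = regulation or RegulationTargets()
    rates = rate_schedule(cfg.sinus_hr, cfg.wenckebach_rate)

    ref_timing = ActivationTiming(cfg.sinus_hr, cfg.pr0)
    ref_model = ClosedLoopModel(phenotype.replace(timing=ref_timing),
                                circulation)
    ref_reg = regulate(ref_model, regulation, initial=warm_state)
    circ, state = ref_reg.circulation, ref_reg.state

    def steady_trace(rate, pr_ms):
        timing = ActivationTiming(rate, min(pr_ms, 400.0))
        model = ClosedLoopModel(phenotype.replace(timing=timing), circ)
        reg = regulate(model, regulation, initial=state)
        res = ClosedLoopModel(model.phenotype, reg.circulation).simulate(
            until_steady=True, initial=reg.state, max_beats=60)
        return res, reg.converged

    plan = [("sinus", None)]
    for r in rates:
        if r >= cfg.wenckebach_rate:
            continue  # Wenckebach conduction is not a model behaviour
        plan.append(("paced", r))
        plan.append(("sinus", None))
    n_total = int(round(len(plan) * cfg.segment_s * fs))
    ecg = np.zeros(n_total)
    lap = np.zeros(n_total)
    cs = np.zeros(n_total)
    rng = np.random.default_rng(cfg.seed)

    sinus_res, _ = steady_trace(cfg.sinus_hr, cfg.pr0)
    rows = []
    for si, (kind, rate) in enumerate(plan):
        t0 = si * cfg.segment_s
        hr = cfg.sinus_hr if kind == "sinus" else rate
        pr_ms = cfg.pr0 if kind == "sinus" else min(cfg.pr_profile(rate),
                                                    400.0)
        if kind == "sinus":
            res, converged = sinus_res, True
        else:
            try:
                res, converged = steady_trace(rate, pr_ms)
            except Exception:
                rows.append({"kind": kind, "rate": rate, "start_s": t0,
                             "converged": False, "mlap": np.nan,
                             "pr_ms": pr_ms})
                continue
        beat = res.trajectory["p_la"].to_numpy()[:-1]
        cl = 60.0 / hr
        n_seg = int(round(cfg.segment_s * fs))
        s0 = int(round(t0 * fs))
        tiled = np.tile(beat, int(np.ceil(n_seg / len(beat))) + 1)[:n_seg]
        lap[s0:s0 + n_seg] = tiled
        onsets = _beat_times(t0, t0 + cfg.segment_s, cl)
        for ta in onsets:
            tv = ta + pr_ms / 1000.0
            if kind == "sinus":
                _add_bump(ecg, fs, ta + cfg.p_offset / 1000.0, cfg.p_sigma,
                          cfg.p_amp)
            else:
                k0 = int(round(ta * fs))
                w = max(int(round(0.001 * fs)), 1)
                if k0 + 2 * w <= n_total:
                    cs[k0:k0 + w] += cfg.spike_amp
                    cs[k0 + w:k0 + 2 * w] -= cfg.spike_amp
            for amp, sig, off in ((cfg.q_amp, cfg.q_sigma, cfg.q_offset),
                                  (cfg.r_amp, cfg.r_sigma, cfg.r_offset),
                                  (cfg.s_amp, cfg.s_sigma, cfg.s_offset)):
                _add_bump(ecg, fs, tv + off / 1000.0, sig, amp)
            _add_bump(ecg, fs, tv + 0.10 + 0.18 * cl, cfg.t_sigma, cfg.t_amp)
        rows.append({"kind": kind, "rate": rate, "start_s": t0,
                     "converged": converged,
                     "mlap": res.metrics.mlap,
                     "peak_lap": res.metrics.peak_lap,
                     "pr_ms": pr_ms})
    ecg += rng.normal(0, cfg.ecg_noise_sd, n_total)
    cs += rng.normal(0, cfg.cs_noise_sd, n_total)
    rec = Recording(sample_rate=fs, ecg=ecg, lap=lap, cs=cs,
                    patient_id=f"model-{cfg.seed}")
    return rec, pd.DataFrame(rows)
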