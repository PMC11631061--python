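"""Clinical pacing-protocol analysis.

Segments the alternating 30-s sinus/paced recording from the pacing-spike
train, averages LA pressure over the final 10 s of every segment (transient
effects of a pacemaker-setting change die out earlier), differences each
paced window against the mean of its two flanking sinus windows, measures
per-beat PR intervals, and assembles the per-patient result: per-rate mLAP
and PR, the optimal rate (lowest mLAP), and the maximum rate (last rate
before Wenckebach block).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError
from .signals import (PanTompkinsResult, detect_pacing_spikes, pan_tompkins,
                      preprocess_ecg)

__all__ = ["Recording", "ProtocolSegment", "BeatAnnotation", "PatientResult",
           "segment_protocol", "mlap_response", "pr_intervals",
           "PacingProtocolAnalysis"]

log = logging.getLogger("atriapace.protocol")


@dataclass
class Recording:
    """Multichannel clinical-style recording (ECG mV, LAP mmHg, CS mV)."""

    sample_rate: float
    ecg: np.ndarray
    lap: np.ndarray
    cs: np.ndarray
    patient_id: str = "anon"

    def __post_init__(self):
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.lap = np.asarray(self.lap, dtype=float)
        self.cs = np.asarray(self.cs, dtype=float)
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be > 0")
        if not (len(self.ecg) == len(self.lap) == len(self.cs)):
            raise DataError("all channels must have equal length")

    def __len__(self):
        return len(self.ecg)


@dataclass(frozen=True)
class ProtocolSegment:
    """One protocol stretch; indices half-open [start, end)."""

    kind: str                       # "sinus" | "paced"
    start: int
    end: int
    pacing_rate: Optional[float] = None
    analysis_window: Tuple[int, int] = (0, 0)

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class BeatAnnotation:
    """Per-beat electrical annotation (sample indices, PR in ms)."""

    r_peak: int
    qrs_onset: int
    atrial_onset: Optional[int]
    pr_ms: Optional[float]
    paced: bool
    dropped: bool = False


def segment_protocol(spikes: np.ndarray, r_peaks: np.ndarray,
                     sample_rate: float,
                     n_samples: int) -> List[ProtocolSegment]:
    """Split the recording into alternating sinus and paced segments.

    Contiguous spike stretches (inter-spike gap below twice the running
    pacing interval) become paced segments with rate = 60/median interval
    rounded to the nearest 10 bpm; the gaps between them become sinus
    segments.  Every segment's analysis window is its final 10 s.
    """
    fs = float(sample_rate)
    win = int(round(10.0 * fs))

    def with_window(kind, start, end, rate=None):
        ws = max(start, end - win)
        return ProtocolSegment(kind=kind, start=int(start), end=int(end),
                               pacing_rate=rate,
                               analysis_window=(int(ws), int(end)))

    spikes = np.asarray(spikes, dtype=int)
    if len(spikes) < 2:
        warnings.warn("no pacing spikes found; treating the whole recording "
                      "as sinus rhythm", stacklevel=2)
        return [with_window("sinus", 0, n_samples)]

    # group spikes into stretches
    stretches = []
    cur = [spikes[0]]
    # the slowest protocol rate is 60 bpm, so a fresh stretch assumes a
    # 1-s pacing interval until it has its own inter-spike statistics
    for s in spikes[1:]:
        interval = (np.median(np.diff(cur)) if len(cur) > 1
                    else 1.0 * sample_rate)
        if s - cur[-1] < 2.0 * interval:
            cur.append(s)
        else:
            stretches.append(cur)
            cur = [s]
    stretches.append(cur)
    stretches = [st for st in stretches if len(st) >= 3]

    segments: List[ProtocolSegment] = []
    pos = 0
    for st in stretches:
        isi = float(np.median(np.diff(st)))
        rate = round(60.0 / (isi / fs) / 10.0) * 10.0
        start = int(st[0])
        end = min(int(st[-1] + isi), n_samples)
        if start > pos:
            segments.append(with_window("sinus", pos, start))
        segments.append(with_window("paced", start, end, rate))
        pos = end
    if pos < n_samples:
        segments.append(with_window("sinus", pos, n_samples))
    # length sanity (30 s +/- 10%) is informative, not fatal
    for seg in segments:
        dur = seg.n_samples / fs
        if seg.kind == "paced" and not 27.0 <= dur <= 33.0:
            log.info("paced segment at %s bpm has unusual length %.1f s",
                     seg.pacing_rate, dur)
    return segments


def mlap_response(lap: np.ndarray,
                  segments: Sequence[ProtocolSegment]) -> pd.DataFrame:
    """Per-rate mLAP and DmLAP against the flanking sinus windows.

    Segment mLAP is the mean of the LA pressure over the segment's analysis
    window only.  DmLAP(rate) = paced mLAP minus the mean of the two
    flanking sinus-window mLAPs; at protocol edges a single flank is used
    and flagged.
    """
    lap = np.asarray(lap, dtype=float)
    if lap.size == 0:
        raise DataError("LA pressure channel is missing or empty")

    def wmean(seg):
        a, b = seg.analysis_window
        return float(lap[a:b].mean())

    rows = []
    for i, seg in enumerate(segments):
        if seg.kind != "paced":
            continue
        prev_sin = next((segments[j] for j in range(i - 1, -1, -1)
                         if segments[j].kind == "sinus"), None)
        next_sin = next((segments[j] for j in range(i + 1, len(segments))
                         if segments[j].kind == "sinus"), None)
        flanks = [s for s in (prev_sin, next_sin) if s is not None]
        if not flanks:
            raise DataError("paced segment has no sinus flank")
        m = wmean(seg)
        sinus_m = float(np.mean([wmean(s) for s in flanks]))
        rows.append({"rate": seg.pacing_rate, "mlap": m,
                     "dmlap": m - sinus_m,
                     "single_flank": len(flanks) == 1})
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.groupby("rate", as_index=False).agg(
            mlap=("mlap", "mean"), dmlap=("dmlap", "mean"),
            single_flank=("single_flank", "any"))
    return df


def _qrs_onset(envelope: np.ndarray, r_peak: int, fs: float) -> int:
    """Back-scan from the R peak for the point where the 10-ms slope of the
    Pan-Tompkins envelope falls below 5% of its local maximum."""
    w = max(int(round(0.010 * fs)), 1)
    back = int(round(0.080 * fs))
    lo = max(r_peak - back, w)
    seg = np.arange(lo, r_peak + 1)
    if len(seg) == 0:
        return max(r_peak - back, 0)
    slopes = envelope[seg] - envelope[seg - w]
    smax = slopes.max()
    if smax <= 0:
        return lo
    k = len(seg) - 1
    while k > 0 and slopes[k] >= 0.05 * smax:
        k -= 1
    return int(seg[k])


def _p_onset(ecg: np.ndarray, qrs_onset: int, fs: float) -> Optional[int]:
    """P-wave onset via a derivative/amplitude threshold in the
    300-50 ms pre-QRS window."""
    lo = qrs_onset - int(round(0.300 * fs))
    hi = qrs_onset - int(round(0.050 * fs))
    if lo < 0 or hi <= lo:
        return None
    w = ecg[lo:hi]
    pk = int(np.argmax(np.abs(w)))
    amp = abs(w[pk])
    if amp < 1e-6:
        return None
    k = pk
    while k > 0 and abs(w[k]) >= 0.1 * amp:
        k -= 1
    return int(lo + k)


def pr_intervals(filtered_ecg: np.ndarray, r_peaks: np.ndarray,
                 spikes: np.ndarray, sample_rate: float,
                 pt: Optional[PanTompkinsResult] = None
                 ) -> List[BeatAnnotation]:
    """Annotate every beat with QRS onset, atrial onset, and PR interval.

    Atrial onset is the nearest preceding pacing spike (paced beats) or the
    detected P-wave onset (intrinsic beats).  A spike with no following QRS
    within one pacing cycle is emitted as a dropped beat.  PR values outside
    (40, 400) ms are flagged (``pr_ms`` set to None) rather than used.
    """
    fs = float(sample_rate)
    if pt is None:
        pt = pan_tompkins(filtered_ecg, fs)
    env = pt.envelope
    spikes = np.asarray(spikes, dtype=int)
    r_peaks = np.asarray(r_peaks, dtype=int)
    cycle = float(np.median(np.diff(spikes))) if len(spikes) > 1 else np.inf

    beats: List[BeatAnnotation] = []
    skipped = 0
    used_spikes = set()
    for r in r_peaks:
        onset = _qrs_onset(env, int(r), fs)
        prev = spikes[spikes < onset]
        spike = int(prev[-1]) if len(prev) else None
        if spike is not None and onset - spike <= 1.2 * cycle:
            atr, paced = spike, True
            used_spikes.add(spike)
        else:
            atr, paced = _p_onset(filtered_ecg, onset, fs), False
        if atr is None:
            skipped += 1
            continue
        pr = (onset - atr) / fs * 1000.0
        if not 40.0 < pr < 400.0:
            log.info("beat at sample %d: PR %.0f ms outside (40, 400), "
                     "flagged", r, pr)
            beats.append(BeatAnnotation(int(r), onset, atr, None, paced))
            continue
        beats.append(BeatAnnotation(int(r), onset, atr, pr, paced))
    if skipped:
        log.info("%d beats skipped (no atrial event found)", skipped)

    # dropped beats: spikes never answered by a QRS within one cycle
    if len(spikes) and len(r_peaks):
        for s in spikes:
            if s in used_spikes:
                continue
            nxt = r_peaks[r_peaks > s]
            if len(nxt) == 0 or nxt[0] - s > 1.2 * cycle:
                beats.append(BeatAnnotation(
                    r_peak=int(s), qrs_onset=int(s), atrial_onset=int(s),
                    pr_ms=None, paced=True, dropped=True))
    beats.sort(key=lambda b: b.atrial_onset or b.r_peak)
    return beats


@dataclass
class PatientResult:
    """Per-patient outcome of the pacing-protocol analysis."""

    patient_id: str
    sinus_hr: float
    sinus_mlap: float
    table: pd.DataFrame          # per rate: mlap, dmlap, pr_mean, n_beats,
                                 # exceeds_sinus, wenckebach
    optimal_rate: Optional[float]
    max_rate: Optional[float]
    beats: List[BeatAnnotation] = field(default_factory=list)
    segments: List[ProtocolSegment] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Pacing-protocol analysis ({self.patient_id})",
            "-------------------------------------------",
            f"sinus rhythm      {self.sinus_hr:.0f} bpm, "
            f"mLAP {self.sinus_mlap:.2f} mmHg",
            f"optimal rate      {self.optimal_rate} bpm",
            f"maximum rate      {self.max_rate} bpm (pre-Wenckebach)",
            "",
            self.table.to_string(index=False,
                                 float_format=lambda v: f"{v:.2f}"),
        ]
        return "\n".join(lines)


class PacingProtocolAnalysis:
    """End-to-end pipeline bound to one recording; ``fit()`` runs it."""

    def __init__(self, recording: Recording):
        self.recording = recording

    def fit(self) -> PatientResult:
        rec = self.recording
        fs = rec.sample_rate
        ecg = preprocess_ecg(rec.ecg, fs)
        pt = pan_tompkins(ecg, fs)
        spikes = detect_pacing_spikes(rec.cs, fs)
        segments = segment_protocol(spikes, pt.r_peaks, fs, len(rec))
        resp = mlap_response(rec.lap, segments)
        beats = pr_intervals(ecg, pt.r_peaks, spikes, fs, pt=pt)

        # sinus heart rate and mLAP from the sinus analysis windows
        sinus_segs = [s for s in segments if s.kind == "sinus"]
        sinus_mlap = float(np.mean(
            [rec.lap[s.analysis_window[0]:s.analysis_window[1]].mean()
             for s in sinus_segs])) if sinus_segs else np.nan
        rr = []
        for s in sinus_segs:
            a, b = s.analysis_window
            rp = pt.r_peaks[(pt.r_peaks >= a) & (pt.r_peaks < b)]
            rr.extend(np.diff(rp))
        sinus_hr = 60.0 / (np.median(rr) / fs) if rr else np.nan

        # per-rate PR means and Wenckebach flags
        seg_of = np.zeros(len(rec), dtype=int) - 1
        for i, s in enumerate(segments):
            seg_of[s.start:s.end] = i
        per_rate_pr = {}
        per_rate_n = {}
        wenck = set()
        for b in beats:
            pos = b.atrial_onset if b.atrial_onset is not None else b.r_peak
            i = seg_of[min(pos, len(rec) - 1)]
            if i < 0 or segments[i].kind != "paced":
                continue
            rate = segments[i].pacing_rate
            if b.dropped:
                wenck.add(rate)
                continue
            if b.pr_ms is not None:
                per_rate_pr.setdefault(rate, []).append(b.pr_ms)
                per_rate_n[rate] = per_rate_n.get(rate, 0) + 1

        table = resp.copy()
        if not table.empty:
            table["pr_mean"] = table["rate"].map(
                lambda r: float(np.mean(per_rate_pr[r]))
                if r in per_rate_pr else np.nan)
            table["n_beats"] = table["rate"].map(
                lambda r: per_rate_n.get(r, 0))
            table["exceeds_sinus"] = table["mlap"] > sinus_mlap
            table["wenckebach"] = table["rate"].isin(wenck)
            clean = table[~table["wenckebach"]]
            if not clean.empty:
                best = clean["mlap"].min()
                optimal = float(clean.loc[
                    np.isclose(clean["mlap"], best), "rate"].min())
            else:
                optimal = None
            if wenck:
                first_w = min(wenck)
                below = table.loc[table["rate"] < first_w, "rate"]
                max_rate = float(below.max()) if not below.empty else None
            else:
                max_rate = float(table["rate"].max())
        else:
            optimal = max_rate = None
        return PatientResult(patient_id=rec.patient_id, sinus_hr=sinus_hr,
                             sinus_mlap=sinus_mlap, table=table,
                             optimal_rate=optimal, max_rate=max_rate,
                             beats=beats, segments=segments)
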