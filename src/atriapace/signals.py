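"""ECG/pressure signal conditioning and event detection.

Preprocessing follows the clinical pipeline: 0.5-100 Hz band-pass, a 50 Hz
notch (Q = 30), and subtraction of an 800-sample centered moving median for
baseline drift.  All filters are applied zero-phase so onset timings are
not shifted.  QRS detection is a classic Pan-Tompkins chain (5-15 Hz
emphasis, 5-point derivative, squaring, 150-ms moving-window integration,
adaptive signal/noise thresholds with a 200-ms refractory period and
search-back).  Pacing spikes are found on the coronary-sinus channel as
first-difference outliers against a rolling median absolute deviation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import InsufficientDataError, ParameterError

__all__ = ["preprocess_ecg", "pan_tompkins", "detect_r_peaks",
           "detect_pacing_spikes", "PanTompkinsResult"]


def preprocess_ecg(ecg: np.ndarray, sample_rate: float) -> np.ndarray:
    """Band-pass, notch, and de-drift one ECG lead (zero-phase).

    Output has the same length as the input.  ``sample_rate`` must be at
    least 250 Hz so the 100 Hz band edge is below Nyquist.
    """
    if sample_rate < 250:
        raise ParameterError("sample_rate must be >= 250 Hz for the 100 Hz "
                             "band edge")
    x = np.asarray(ecg, dtype=float)
    sos = sps.butter(2, [0.5, 100.0], btype="bandpass", fs=sample_rate,
                     output="sos")
    y = sps.sosfiltfilt(sos, x)
    b, a = sps.iirnotch(50.0, 30.0, fs=sample_rate)
    y = sps.filtfilt(b, a, y)
    med = (pd.Series(y).rolling(800, center=True, min_periods=1)
           .median().to_numpy())
    return y - med


@dataclass
class PanTompkinsResult:
    """R-peaks plus the intermediate signals the onset logic reuses."""

    r_peaks: np.ndarray      # sample indices, strictly increasing
    envelope: np.ndarray     # moving-window integrated energy (causal)
    filtered: np.ndarray     # 5-15 Hz band-passed input


def pan_tompkins(ecg: np.ndarray, sample_rate: float) -> PanTompkinsResult:
    """Pan-Tompkins QRS detection returning peaks and internals."""
    x = np.asarray(ecg, dtype=float)
    fs = float(sample_rate)
    if len(x) < 2 * fs:
        raise InsufficientDataError("need at least 2 s of signal")
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    # 5-point derivative
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(filt, kernel[::-1], mode="same")
    sq = deriv ** 2
    nw = max(int(round(0.150 * fs)), 1)
    # causal moving-window integration: the envelope starts rising at QRS
    # energy onset, which the onset back-scan relies on
    env = np.convolve(sq, np.ones(nw) / nw)[:len(sq)]

    refractory = int(round(0.2 * fs))
    cand, _ = sps.find_peaks(env, distance=refractory)
    if len(cand) == 0:
        return PanTompkinsResult(np.array([], dtype=int), env, filt)

    # adaptive thresholds (initialised from the first 2 s)
    head = env[:int(2 * fs)]
    spki = float(np.max(head)) * 0.4 if head.size else 0.0
    npki = float(np.mean(head)) * 0.5 if head.size else 0.0
    peaks = []
    rr_hist = []

    def accept(idx):
        peaks.append(idx)
        if len(peaks) > 1:
            rr_hist.append(peaks[-1] - peaks[-2])
            if len(rr_hist) > 8:
                rr_hist.pop(0)

    i = 0
    while i < len(cand):
        idx = cand[i]
        amp = env[idx]
        thr = npki + 0.25 * (spki - npki)
        missed = (rr_hist and peaks
                  and idx - peaks[-1] > 1.66 * np.mean(rr_hist))
        if amp > thr:
            spki = 0.125 * amp + 0.875 * spki
            accept(idx)
        else:
            npki = 0.125 * amp + 0.875 * npki
            if missed:
                # search-back with the lower threshold over skipped window
                back = [c for c in cand[max(0, i - 8):i + 1]
                        if c > peaks[-1] + refractory
                        and env[c] > 0.5 * thr]
                if back:
                    b = back[int(np.argmax(env[back]))]
                    spki = 0.25 * env[b] + 0.75 * spki
                    accept(b)
        i += 1

    if not peaks:
        return PanTompkinsResult(np.array([], dtype=int), env, filt)
    # refine each detection to the R peak of the band-passed waveform
    half = int(round(0.075 * fs))
    refined = []
    for pk in peaks:
        lo = max(pk - 2 * half, 0)
        hi = min(pk + half, len(filt))
        refined.append(lo + int(np.argmax(np.abs(filt[lo:hi]))))
    refined = np.array(sorted(set(refined)), dtype=int)
    keep = [0]
    for j in range(1, len(refined)):
        if refined[j] - refined[keep[-1]] >= refractory:
            keep.append(j)
    return PanTompkinsResult(refined[keep], env, filt)


def detect_r_peaks(ecg: np.ndarray, sample_rate: float) -> np.ndarray:
    """R-peak sample indices (strictly increasing)."""
    return pan_tompkins(ecg, sample_rate).r_peaks


def detect_pacing_spikes(cs: np.ndarray, sample_rate: float,
                         threshold_mads: float = 8.0,
                         refractory_ms: float = 100.0) -> np.ndarray:
    """Pacing-spike onsets on the coronary-sinus channel.

    A spike is a first-difference excursion exceeding ``threshold_mads``
    times the rolling (1-s blocks) median absolute deviation, with a 100-ms
    refractory period.  Returns an empty array on a flat channel.
    """
    x = np.asarray(cs, dtype=float)
    if x.size == 0:
        return np.array([], dtype=int)
    d = np.diff(x, prepend=x[0])
    block = max(int(round(sample_rate)), 1)
    nblk = int(np.ceil(len(d) / block))
    pad = nblk * block - len(d)
    db = np.pad(d, (0, pad), mode="edge").reshape(nblk, block)
    med = np.median(db, axis=1)
    mad = np.median(np.abs(db - med[:, None]), axis=1)
    thr = np.repeat(threshold_mads * np.maximum(mad, 1e-12), block)[:len(d)]
    centre = np.repeat(med, block)[:len(d)]
    above = np.abs(d - centre) > thr
    if not above.any():
        return np.array([], dtype=int)
    refractory = int(round(refractory_ms / 1000.0 * sample_rate))
    idx = np.flatnonzero(above)
    spikes = [int(idx[0])]
    for i in idx[1:]:
        if i - spikes[-1] >= refractory:
            spikes.append(int(i))
    return np.array(spikes, dtype=int)
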