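"""ECG preprocessing, Pan-Tompkins detection, pacing-spike detection."""
import numpy as np
import pytest

from atriapace.exceptions import InsufficientDataError, ParameterError
from atriapace.signals import (detect_pacing_spikes, detect_r_peaks,
                               preprocess_ecg)
from atriapace.synth import SyntheticConfig, generate_recording

FS = 1000.0


class TestPreprocess:
    def test_constant_input_maps_to_zero(self):
        out = preprocess_ecg(np.full(20000, 3.7), FS)
        assert np.max(np.abs(out)) < 1e-6

    def test_mains_tone_attenuated_40db(self):
        t = np.arange(30000) / FS
        tone = np.sin(2 * np.pi * 50.0 * t)
        out = preprocess_ecg(tone, FS)
        in_rms = np.sqrt(np.mean(tone[5000:-5000] ** 2))
        out_rms = np.sqrt(np.mean(out[5000:-5000] ** 2))
        assert out_rms / in_rms < 0.01  # >= 40 dB

    def test_passband_10hz_preserved(self):
        t = np.arange(30000) / FS
        tone = np.sin(2 * np.pi * 10.0 * t)
        out = preprocess_ecg(tone, FS)
        mid = slice(5000, -5000)
        amp = np.max(np.abs(out[mid]))
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_preserves_length_and_rejects_low_fs(self):
        x = np.random.default_rng(0).normal(size=5000)
        assert len(preprocess_ecg(x, FS)) == len(x)
        with pytest.raises(ParameterError):
            preprocess_ecg(x, 200.0)


def synthetic_ecg(duration_s=60.0, hr=60.0, noise_sd=None, seed=0):
    """Clean-protocol ECG with known R times at a 20 dB SNR by default."""
    cfg = SyntheticConfig(seed=seed, sinus_hr=hr, mains_amp_ecg=0.0,
                          drift_amp_ecg=0.0)
    rng = np.random.default_rng(seed)
    n = int(duration_s * FS)
    t = np.arange(n) / FS
    ecg = np.zeros(n)
    cl = 60.0 / hr
    r_times = []
    beat = 0.0
    while beat + cl < duration_s:
        tv = beat + cfg.pr0 / 1000.0
        for amp, sig, off in ((cfg.q_amp, cfg.q_sigma, cfg.q_offset),
                              (cfg.r_amp, cfg.r_sigma, cfg.r_offset),
                              (cfg.s_amp, cfg.s_sigma, cfg.s_offset)):
            c = tv + off / 1000.0
            ecg += amp * np.exp(-0.5 * ((t - c) / (sig / 1000.0)) ** 2)
        c = beat + cfg.p_offset / 1000.0
        ecg += cfg.p_amp * np.exp(-0.5 * ((t - c)
                                          / (cfg.p_sigma / 1000.0)) ** 2)
        c = tv + 0.1 + 0.18 * cl
        ecg += cfg.t_amp * np.exp(-0.5 * ((t - c)
                                          / (cfg.t_sigma / 1000.0)) ** 2)
        r_times.append(tv + cfg.r_offset / 1000.0)
        beat += cl
    if noise_sd is None:
        # 20 dB SNR against the QRS amplitude
        noise_sd = cfg.r_amp / 10.0
    ecg += rng.normal(0, noise_sd, n)
    return ecg, np.array(r_times)


class TestPanTompkins:
    def test_zero_signal_yields_no_peaks(self):
        assert len(detect_r_peaks(np.zeros(10000), FS)) == 0

    def test_too_short_signal_raises(self):
        with pytest.raises(InsufficientDataError):
            detect_r_peaks(np.zeros(500), FS)

    def test_sixty_bpm_minute_recovers_all_beats(self):
        ecg, r_true = synthetic_ecg(60.0, 60.0)
        peaks = detect_r_peaks(preprocess_ecg(ecg, FS), FS)
        assert abs(len(peaks) - len(r_true)) <= 1
        # each true R matched within +/-10 ms
        for rt in r_true:
            err = np.min(np.abs(peaks / FS - rt)) * 1000
            assert err <= 10.0

    def test_amplitude_invariance(self):
        ecg, _ = synthetic_ecg(30.0, 70.0)
        x = preprocess_ecg(ecg, FS)
        p1 = detect_r_peaks(x, FS)
        p2 = detect_r_peaks(2.0 * x, FS)
        assert np.array_equal(p1, p2)

    def test_peaks_strictly_increasing(self):
        ecg, _ = synthetic_ecg(30.0, 90.0)
        peaks = detect_r_peaks(preprocess_ecg(ecg, FS), FS)
        assert np.all(np.diff(peaks) > 0)


class TestPacingSpikes:
    def _spike_train(self, rate=100.0, duration=30.0, amp=2.0,
                     noise_sd=0.0, seed=0):
        n = int(duration * FS)
        cs = np.zeros(n)
        interval = 60.0 / rate
        count = int((duration - 0.5) / interval)
        onsets = ((0.25 + np.arange(count) * interval) * FS).astype(int)
        for s in onsets:
            cs[s] += amp
            cs[s + 1] -= amp
        if noise_sd:
            cs += np.random.default_rng(seed).normal(0, noise_sd, n)
        return cs, onsets

    def test_zero_channel_yields_empty(self):
        assert len(detect_pacing_spikes(np.zeros(30000), FS)) == 0

    def test_100bpm_train_recovered_within_2ms(self):
        cs, onsets = self._spike_train(noise_sd=0.01)
        spikes = detect_pacing_spikes(cs, FS)
        assert len(onsets) == 49  # 30 s at 100 bpm starting 0.25 s in
        assert len(spikes) == len(onsets)
        assert np.max(np.abs(spikes - onsets)) <= 2

    def test_noise_at_10pct_of_amplitude_changes_nothing(self):
        cs0, _ = self._spike_train(noise_sd=0.01, seed=1)
        cs1, _ = self._spike_train(noise_sd=0.2, seed=1)  # 10% of 2.0
        s0 = detect_pacing_spikes(cs0, FS)
        s1 = detect_pacing_spikes(cs1, FS)
        assert len(s0) == len(s1)
        assert np.max(np.abs(s0 - s1)) <= 2

    def test_spikes_strictly_increasing_with_refractory(self):
        cs, _ = self._spike_train(rate=140.0)
        spikes = detect_pacing_spikes(cs, FS)
        assert np.all(np.diff(spikes) >= 0.1 * FS)


class TestEndToEndDetectionOnFullProtocol:
    def test_spike_onsets_match_truth(self):
        rec, truth = generate_recording(SyntheticConfig(seed=5))
        spikes = detect_pacing_spikes(rec.cs, rec.sample_rate)
        true_onsets = truth.beats.loc[truth.beats.paced,
                                      "atrial_onset"].to_numpy()
        assert len(spikes) == len(true_onsets)
        assert np.max(np.abs(spikes - true_onsets)) <= 2
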