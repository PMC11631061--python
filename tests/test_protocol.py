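"""Protocol segmentation, mLAP differencing, PR measurement, patient result."""
import numpy as np
import pytest

from atriapace.exceptions import DataError
from atriapace.protocol import (PacingProtocolAnalysis, Recording,
                                mlap_response, pr_intervals,
                                segment_protocol)
from atriapace.signals import pan_tompkins, preprocess_ecg
from atriapace.synth import SyntheticConfig, generate_recording

FS = 1000.0


def spike_train(start_s, duration_s, interval_s):
    return (np.arange(start_s, start_s + duration_s - 1e-9, interval_s)
            * FS).astype(int)


class TestSegmentation:
    def test_single_paced_block_with_sinus_flanks(self):
        spikes = spike_train(30.0, 30.0, 0.6)  # 100 bpm
        segs = segment_protocol(spikes, np.array([]), FS, int(90 * FS))
        kinds = [s.kind for s in segs]
        assert kinds == ["sinus", "paced", "sinus"]
        paced = segs[1]
        assert paced.pacing_rate == 100.0
        ws, we = paced.analysis_window
        assert we == paced.end and we - ws == int(10 * FS)

    def test_full_protocol_schedule_recovered(self):
        rec, truth = generate_recording(SyntheticConfig(seed=7))
        from atriapace.signals import detect_pacing_spikes
        spikes = detect_pacing_spikes(rec.cs, FS)
        segs = segment_protocol(spikes, np.array([]), FS, len(rec))
        rates = [s.pacing_rate for s in segs if s.kind == "paced"]
        assert rates == [60.0, 70.0, 80.0, 90.0, 100.0, 110.0, 120.0,
                         130.0, 140.0]

    def test_short_paced_segment_tolerated(self):
        spikes = spike_train(30.0, 29.5, 0.6)
        segs = segment_protocol(spikes, np.array([]), FS, int(90 * FS))
        assert [s.kind for s in segs] == ["sinus", "paced", "sinus"]

    def test_no_spikes_single_sinus_segment_with_warning(self):
        with pytest.warns(UserWarning, match="no pacing spikes"):
            segs = segment_protocol(np.array([]), np.array([]), FS,
                                    int(60 * FS))
        assert len(segs) == 1 and segs[0].kind == "sinus"


class TestMlapResponse:
    def test_constant_lap_gives_zero_dmlap(self):
        spikes = spike_train(30.0, 30.0, 0.6)
        segs = segment_protocol(spikes, np.array([]), FS, int(90 * FS))
        lap = np.full(int(90 * FS), 12.0)
        df = mlap_response(lap, segs)
        assert df["dmlap"].iloc[0] == pytest.approx(0.0)
        assert df["mlap"].iloc[0] == pytest.approx(12.0)

    def test_flanking_sinus_mean_subtracted(self):
        spikes = spike_train(30.0, 30.0, 0.6)
        segs = segment_protocol(spikes, np.array([]), FS, int(90 * FS))
        lap = np.full(int(90 * FS), 10.0)
        lap[:int(30 * FS)] = 8.0           # pre-pacing sinus
        lap[int(60 * FS):] = 12.0          # post-pacing sinus
        df = mlap_response(lap, segs)
        # paced mLAP 10 vs flank mean (8+12)/2 = 10
        assert df["dmlap"].iloc[0] == pytest.approx(0.0)
        assert not df["single_flank"].iloc[0]

    def test_window_discipline(self):
        """Samples outside the analysis window must not contribute."""
        spikes = spike_train(30.0, 30.0, 0.6)
        segs = segment_protocol(spikes, np.array([]), FS, int(90 * FS))
        lap = np.full(int(90 * FS), 10.0)
        paced = segs[1]
        ws = paced.analysis_window[0]
        # corrupt the paced segment OUTSIDE its window
        lap[paced.start:ws] = 99.0
        df = mlap_response(lap, segs)
        assert df["mlap"].iloc[0] == pytest.approx(10.0)

    def test_missing_lap_channel_raises(self):
        spikes = spike_train(30.0, 30.0, 0.6)
        segs = segment_protocol(spikes, np.array([]), FS, int(90 * FS))
        with pytest.raises(DataError):
            mlap_response(np.array([]), segs)


class TestPRIntervals:
    def test_spike_to_qrs_onset_interval(self):
        """A spike at 1 s followed by a QRS whose onset sits ~200 ms later
        must yield PR ~= 200 ms."""
        n = int(10 * FS)
        t = np.arange(n) / FS
        ecg = np.zeros(n)
        spikes = []
        for beat_s in np.arange(1.0, 9.0, 1.0):
            spikes.append(int(beat_s * FS))
            tv = beat_s + 0.200
            for amp, sig, off in ((-0.12, 5.0, 12.0), (1.0, 11.0, 32.0),
                                  (-0.2, 6.0, 52.0)):
                c = tv + off / 1000.0
                ecg += amp * np.exp(-0.5 * ((t - c) / (sig / 1000.0)) ** 2)
        x = preprocess_ecg(ecg, FS)
        pt = pan_tompkins(x, FS)
        beats = pr_intervals(x, pt.r_peaks, np.array(spikes), FS, pt=pt)
        prs = [b.pr_ms for b in beats if b.pr_ms is not None]
        assert len(prs) >= 6
        assert np.mean(prs) == pytest.approx(200.0, abs=10.0)

    def test_programmed_pr_prolongation_recovered(self):
        rec, truth = generate_recording(SyntheticConfig(seed=11))
        res = PacingProtocolAnalysis(rec).fit()
        tab = res.table.set_index("rate")
        for rate, pr_true in truth.pr_per_rate.items():
            measured = tab.loc[rate, "pr_mean"]
            assert measured == pytest.approx(pr_true, abs=10.0)

    def test_retained_pr_values_in_physiologic_range(self):
        rec, _ = generate_recording(SyntheticConfig(seed=3))
        res = PacingProtocolAnalysis(rec).fit()
        prs = np.array([b.pr_ms for b in res.beats if b.pr_ms is not None])
        assert ((prs > 40.0) & (prs < 400.0)).all()

    def test_dropped_beats_flagged_at_wenckebach_rate(self):
        rec, truth = generate_recording(SyntheticConfig(seed=4))
        res = PacingProtocolAnalysis(rec).fit()
        dropped = [b for b in res.beats if b.dropped]
        n_true = int(truth.beats.dropped.sum())
        assert n_true > 0
        assert len(dropped) == pytest.approx(n_true, abs=2)
        assert res.table.loc[res.table.rate == 140.0,
                             "wenckebach"].iloc[0]


class TestPatientResult:
    def test_pipeline_is_deterministic(self):
        rec, _ = generate_recording(SyntheticConfig(seed=21))
        a = PacingProtocolAnalysis(rec).fit()
        b = PacingProtocolAnalysis(rec).fit()
        assert a.table.equals(b.table)
        assert a.optimal_rate == b.optimal_rate

    def test_optimal_and_max_rate_definitions(self):
        rec, truth = generate_recording(SyntheticConfig(seed=13))
        res = PacingProtocolAnalysis(rec).fit()
        assert res.optimal_rate == truth.optimal_rate
        assert res.max_rate == truth.max_rate
        tab = res.table[~res.table["wenckebach"]]
        assert res.optimal_rate == tab.loc[tab["mlap"].idxmin(), "rate"]

    def test_recording_channel_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            Recording(FS, np.zeros(100), np.zeros(99), np.zeros(100))
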