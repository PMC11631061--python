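"""Closed-loop model: conservation, steady state, oracle, and metrics."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from atriapace.exceptions import ParameterError
from atriapace.metrics import TRAJ_COLUMNS, beat_metrics
from atriapace.model import (ActivationTiming, ClosedLoopModel,
                             PhenotypeConfig, normal_chambers)
from atriapace.regulation import regulate

VOL_COLS = [f"v_{c}" for c in
            ("la", "lv", "ra", "rv", "sa", "sv", "pa", "pv")]


@pytest.fixture(scope="module")
def normal_steady():
    ph = PhenotypeConfig(timing=ActivationTiming(54, 153))
    model = ClosedLoopModel(ph)
    reg = regulate(model)
    res = ClosedLoopModel(ph, reg.circulation).simulate(
        until_steady=True, initial=reg.state)
    return model, reg, res


class TestTimingTypes:
    def test_cycle_length_consistent(self):
        t = ActivationTiming(60, 150)
        assert t.cycle_length == pytest.approx(1000.0)

    @pytest.mark.parametrize("hr,pr", [(20, 150), (300, 150), (60, 450),
                                       (60, -5)])
    def test_out_of_range_rejected(self, hr, pr):
        with pytest.raises(ParameterError):
            ActivationTiming(hr, pr)


class TestConservation:
    def test_volume_conserved_over_50_beats(self):
        ph = PhenotypeConfig(timing=ActivationTiming(54, 153))
        model = ClosedLoopModel(ph)
        state = model.initial_state()
        total0 = state.volumes.sum()
        worst = 0.0
        y = state.y
        for _ in range(50):
            Y, AUX, y = model.run_cycle(y)
            tot = Y[:, :8].sum(axis=1)
            worst = max(worst, np.max(np.abs(tot - total0)) / total0)
        assert worst < 1e-6

    def test_trajectory_sums_to_total_volume(self, normal_steady):
        model, reg, res = normal_steady
        tot = res.trajectory[VOL_COLS].sum(axis=1).to_numpy()
        vtot = reg.circulation.total_blood_volume
        assert np.max(np.abs(tot - vtot)) / vtot < 1e-6


class TestSteadyState:
    def test_periodicity_at_steady_state(self, normal_steady):
        _, _, res = normal_steady
        assert res.steady
        a, b = res.onset_states[-2][:8], res.onset_states[-1][:8]
        assert np.max(np.abs(b - a) / np.abs(a)) < 1e-3

    def test_flow_consistency(self, normal_steady):
        """Beat-averaged aortic flow = mitral flow = CO within 1%."""
        _, _, res = normal_steady
        body = res.trajectory.iloc[:-1]
        q_ao = body["q_ao"].mean() * 60 / 1000
        q_mit = body["q_mit"].mean() * 60 / 1000
        co = res.metrics.co
        assert q_ao == pytest.approx(co, rel=0.01)
        assert q_mit == pytest.approx(co, rel=0.01)

    def test_no_pump_without_active_elastance(self):
        ph = PhenotypeConfig(timing=ActivationTiming(54, 153))
        model = ClosedLoopModel(ph, active=False)
        res = model.simulate(n_beats=60)
        body = res.trajectory.iloc[:-1]
        assert body["q_ao"].mean() * 60 / 1000 < 0.05  # L/min
        pressures = body[["p_la", "p_lv", "p_ra", "p_rv",
                          "p_sa", "p_sv", "p_pa", "p_pv"]].iloc[-1]
        assert pressures.max() - pressures.min() < 1.0


class TestStaticEquilibriumOracle:
    def test_open_loop_matches_closed_form_rc_solution(self):
        """With constant (zero) activation and valves locked open the loop
        must relax to the analytic uniform-pressure equilibrium."""
        ph = PhenotypeConfig(timing=ActivationTiming(54, 153),
                             pericardial_constraint_enabled=False)
        model = ClosedLoopModel(ph, valves_open=True, active=False)
        res = model.simulate(until_steady=True, steady_tol=1e-6,
                             max_beats=200)
        final = res.trajectory.iloc[-1][["p_la", "p_lv", "p_ra", "p_rv",
                                         "p_sa", "p_sv", "p_pa", "p_pv"]]

        # independent closed-form solve: sum of V_i(p) = V_tot
        ch = normal_chambers()
        c = model.circulation

        def total_volume(p):
            tot = 0.0
            for name in ("la", "lv", "ra", "rv"):
                cp = ch[name]
                tot += cp.unstressed_volume * (
                    1 + np.log(p / cp.passive_ref_pressure + 1)
                    / cp.passive_stiffness_exponent)
            for cc, v0 in ((c.c_sa, c.v0_sa), (c.c_sv, c.v0_sv),
                           (c.c_pa, c.v0_pa), (c.c_pv, c.v0_pv)):
                tot += v0 + cc * p
            return tot

        p_star = brentq(lambda p: total_volume(p)
                        - c.total_blood_volume, 0.01, 50.0)
        assert np.max(np.abs(final - p_star) / p_star) < 0.005


class TestPhenotypeEffects:
    def test_stiffness_raises_mlap(self, normal_steady):
        model, reg, res = normal_steady

        def mlap(scale):
            ph = PhenotypeConfig(lv_passive_stiffness_scale=scale,
                                 timing=ActivationTiming(54, 153))
            m = ClosedLoopModel(ph, reg.circulation)
            r = regulate(m, initial=reg.state)
            return ClosedLoopModel(ph, r.circulation).simulate(
                until_steady=True, initial=r.state).metrics.mlap

        m1, m2, m3 = mlap(1.0), mlap(2.0), mlap(3.0)
        assert m1 < m2 < m3

    def test_atrial_myopathy_weakens_a_wave_and_raises_mlap(
            self, normal_steady):
        model, reg, res = normal_steady
        ph = PhenotypeConfig(atrial_contractility_fraction=0.5,
                             timing=ActivationTiming(54, 153))
        m = ClosedLoopModel(ph, reg.circulation)
        r = regulate(m, initial=reg.state)
        myo = ClosedLoopModel(ph, r.circulation).simulate(
            until_steady=True, initial=r.state)
        assert myo.metrics.a_peak < res.metrics.a_peak
        assert myo.metrics.mlap > res.metrics.mlap


class TestBeatMetrics:
    def _frame(self, n=1000, **overrides):
        data = {c: np.zeros(n + 1) for c in TRAJ_COLUMNS}
        data["time_ms"] = np.arange(n + 1, dtype=float)
        data["v_la"] = np.full(n + 1, 60.0)
        data["v_lv"] = np.full(n + 1, 120.0)
        data.update(overrides)
        return pd.DataFrame(data)

    def test_constant_lap_gives_its_mean(self):
        frame = self._frame(p_la=np.full(1001, 10.0))
        m = beat_metrics(frame, heart_rate=60.0, pr_interval_ms=150.0)
        assert m.mlap == pytest.approx(10.0)
        assert m.peak_lap == pytest.approx(10.0)

    def test_co_equals_sv_times_rate(self):
        v_lv = 120.0 - 40.0 * np.sin(np.linspace(0, np.pi, 1001))
        frame = self._frame(v_lv=v_lv)
        m = beat_metrics(frame, heart_rate=60.0, pr_interval_ms=0.0)
        assert m.co == pytest.approx(m.sv * 60.0 / 1000.0, rel=1e-12)
        assert m.lvedv >= m.sv

    def test_single_unbroken_diastolic_wave_flags_fusion(self):
        t = np.arange(1001, dtype=float)
        q = 300.0 * np.exp(-0.5 * ((t - 700) / 60) ** 2)
        frame = self._frame(q_mit=q)
        m = beat_metrics(frame, heart_rate=60.0, pr_interval_ms=150.0)
        assert m.ea_fused

    def test_distinct_e_and_a_waves_measured(self):
        t = np.arange(1001, dtype=float)
        q = (300.0 * np.exp(-0.5 * ((t - 550) / 50) ** 2)
             + 200.0 * np.exp(-0.5 * ((t - 950) / 40) ** 2))
        frame = self._frame(q_mit=q)
        m = beat_metrics(frame, heart_rate=60.0, pr_interval_ms=150.0)
        assert not m.ea_fused
        assert m.e_peak == pytest.approx(300.0, rel=0.05)
        assert m.a_peak == pytest.approx(200.0, rel=0.05)
        assert m.ea_ratio == pytest.approx(1.5, rel=0.1)

    def test_non_periodic_input_warns(self):
        v_la = np.linspace(60, 80, 1001)
        frame = self._frame(v_la=v_la)
        with pytest.warns(UserWarning, match="non-periodic"):
            beat_metrics(frame, heart_rate=60.0, pr_interval_ms=150.0)


class TestCannonWave:
    def test_long_pr_at_140_bpm_raises_peak_lap(self, hfpef_sweeps):
        """Atrial contraction against a closed mitral valve (PR >= 250 ms at
        140 bpm) must produce a higher LA pressure peak than PR = 100 ms."""
        grid = hfpef_sweeps["normal"].grid
        at = lambda pr: grid[(grid.rate == 140)
                             & (grid.pr == pr)].peak_lap.iloc[0]
        assert at(250) > at(100)
        assert at(300) > at(100)
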