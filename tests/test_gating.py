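import numpy as np
import pytest
from dataclasses import replace

import mscmech as m
from mscmech.errors import (
    BaselineError,
    InsufficientDataError,
    InvalidInputError,
    NoActivationError,
    UndefinedConductanceError,
)

from conftest import square_pulse_trace


class TestIdealizer:
    def test_noiseless_square_pulse(self):
        trace = square_pulse_trace(amplitude=10.0, start=100, stop=200)
        ideal = m.idealize(trace)
        assert ideal.n_transitions == 2
        assert ideal.unitary_amplitude == pytest.approx(10.0)
        np.testing.assert_allclose(ideal.transition_times,
                                   trace.time[[100, 200]])
        assert list(ideal.levels) == [0, 1, 0]

    def test_flat_noise_only(self):
        rng = np.random.default_rng(0)
        n = 2000
        trace = m.RecordingTrace(
            time=np.arange(n) / 1000.0, current=rng.normal(0, 0.5, n),
            pressure=np.zeros(n), sampling_rate=1000.0, voltage=30.0)
        ideal = m.idealize(trace)
        assert ideal.n_transitions == 0

    def test_too_short(self):
        with pytest.raises(InvalidInputError):
            m.idealize(square_pulse_trace(n=5, start=1, stop=3))

    def test_no_baseline_segment(self):
        n = 500
        trace = m.RecordingTrace(
            time=np.arange(n) / 1000.0, current=np.zeros(n),
            pressure=np.full(n, -80.0), sampling_rate=1000.0, voltage=30.0)
        with pytest.raises(BaselineError):
            m.idealize(trace)

    def test_seeded_event_recovery(self, simulate_sweep, nonvolt_mscCG):
        """>= 95% of events longer than 2 ms recovered within one sample."""
        # hold near the activation midpoint so the channel flickers
        hold = 2 * 5.5 / 0.9 / 0.133322  # mmHg giving T = T_half on r=0.9 um
        trace, events = simulate_sweep(
            [nonvolt_mscCG], seed=17, kind="step", peak=-hold, duration=20.0,
            sampling_rate=2000.0, noise_sd=0.5)
        ideal = m.idealize(trace)
        dt = 1.0 / trace.sampling_rate
        times = np.array([e.time_s for e in events])
        dwells = np.diff(np.append(times, trace.time[-1]))
        long_events = times[dwells > 0.002]
        assert len(long_events) >= 10
        hits = sum(
            np.min(np.abs(ideal.transition_times - t)) <= dt + 1e-12
            for t in long_events)
        assert hits / len(long_events) >= 0.95

    def test_substate_occupancy_reported(self, simulate_sweep):
        # full-open amplitude 1.0 nS x 30 mV; the 0.5 substate is ambiguous
        # for blind mode separation, so the full amplitude is hinted
        trace, _ = simulate_sweep("mscCG2", seed=3, peak=-240, voltage=30.0)
        ideal = m.idealize(trace, unitary_amplitude_hint=30.0)
        assert ideal.substate_occupancy > 0.05
        trace2, _ = simulate_sweep("cgmscl", seed=3, peak=-240, voltage=30.0)
        assert m.idealize(trace2).substate_occupancy < 0.02


class TestUnitaryConductance:
    def test_worked_values(self):
        trace = square_pulse_trace(amplitude=10.2)
        assert m.unitary_conductance(m.idealize(trace), 30.0) == \
            pytest.approx(0.34, abs=1e-9)
        trace = square_pulse_trace(amplitude=30.0)
        assert m.unitary_conductance(m.idealize(trace), 30.0) == \
            pytest.approx(1.0, abs=1e-9)

    def test_zero_amplitude_is_zero(self):
        rng = np.random.default_rng(1)
        n = 1000
        trace = m.RecordingTrace(
            time=np.arange(n) / 1000.0, current=rng.normal(0, 0.3, n),
            pressure=np.zeros(n), sampling_rate=1000.0, voltage=30.0)
        assert m.unitary_conductance(m.idealize(trace), 30.0) == 0.0

    def test_zero_voltage(self):
        trace = square_pulse_trace()
        with pytest.raises(UndefinedConductanceError):
            m.unitary_conductance(m.idealize(trace), 0.0)

    def test_sign_invariant_for_nonrectifying(self, simulate_sweep):
        spec = replace(m.PRESETS["cgmscl"], voltage_coupling=0.0)
        g = {}
        for v in (30.0, -30.0):
            trace, _ = simulate_sweep([spec], seed=9, peak=-240, voltage=v)
            g[v] = m.unitary_conductance(m.idealize(trace), v)
        assert g[30.0] == pytest.approx(g[-30.0], rel=0.02)


class TestOpenProbability:
    def test_always_closed_and_always_open(self):
        trace = square_pulse_trace(amplitude=10.0, n=400, start=100, stop=400)
        ideal = m.idealize(trace)
        assert m.open_probability(ideal, (0.0, 0.05)) == 0.0
        assert m.open_probability(ideal, (0.15, 0.35)) == pytest.approx(1.0)

    def test_brute_force_equivalence(self, simulate_sweep, nonvolt_mscCG):
        trace, _ = simulate_sweep([nonvolt_mscCG], seed=5, peak=-150,
                                  duration=4.0, sampling_rate=2000.0)
        ideal = m.idealize(trace)
        levels = ideal.level_at(trace.time)
        window = (trace.time[0], trace.time[-1])
        brute = np.mean(levels[:-1])  # uniform sampling; last edge excluded
        assert m.open_probability(ideal, window) == pytest.approx(brute,
                                                                  abs=2e-3)

    def test_stationary_chain_matches_generator(self, patch_geometry,
                                                nonvolt_mscCG):
        """NPo over 60 s matches the two-state stationary occupancy 0.3."""
        beta = nonvolt_mscCG.sensitivity
        target = 0.3
        dT = np.log(target / (1 - target)) / (2 * beta)
        hold = 2 * (5.5 + dT) / 0.9 / 0.133322
        protocol = m.build_protocol("step", -hold, 60.0, 1000.0, lead=0.5,
                                    levels=[-hold])
        trace, _ = m.simulate_recording([nonvolt_mscCG], protocol,
                                        patch_geometry, 30.0,
                                        m.NoiseSpec(seed=11))
        npo = m.open_probability(m.idealize(trace), (0.5, 60.5))
        # 3 standard errors of a 60 s average with ~0.1 s correlation time
        assert npo == pytest.approx(target, abs=0.09)

    def test_empty_window(self):
        ideal = m.idealize(square_pulse_trace())
        with pytest.raises(InvalidInputError):
            m.open_probability(ideal, (0.2, 0.1))


class TestThresholds:
    def test_first_opening_matches_laplace_inversion(self, simulate_sweep,
                                                     nonvolt_mscCG):
        """First openings concentrate near P = 2 T_half / r on slow ramps."""
        expected = -2 * 5.5 / 0.9 / 0.133322   # ~ -91.7 mmHg
        pressures = []
        for seed in range(10):
            trace, _ = simulate_sweep([nonvolt_mscCG], seed=seed, peak=-150,
                                      duration=8.0)
            ideal = m.idealize(trace)
            pressures.append(m.first_opening_pressure(trace, ideal))
        assert np.mean(pressures) == pytest.approx(expected, rel=0.10)
        # band reported for MscCG activation on 0.9 um patches
        assert -105 <= np.mean(pressures) <= -85

    def test_opening_before_suction_reads_zero_pressure(self):
        # opening while the protocol still sits at zero pressure
        trace = square_pulse_trace(amplitude=10.0, n=400, start=30, stop=60)
        ideal = m.idealize(trace)
        assert m.first_opening_pressure(trace, ideal) == 0.0

    def test_no_activation(self):
        rng = np.random.default_rng(2)
        n = 1000
        trace = m.RecordingTrace(
            time=np.arange(n) / 1000.0, current=rng.normal(0, 0.4, n),
            pressure=np.linspace(0, -50, n), sampling_rate=1000.0,
            voltage=30.0)
        with pytest.raises(NoActivationError):
            m.first_opening_pressure(trace, m.idealize(trace))

    @pytest.mark.parametrize("p_ref, p_ch, expected", [
        (-220.0, -100.0, 2.2),
        (-226.0, -226.0, 1.0),
    ])
    def test_threshold_ratio(self, p_ref, p_ch, expected):
        assert m.threshold_ratio(p_ref, p_ch) == pytest.approx(expected)

    def test_threshold_ratio_zero_denominator(self):
        with pytest.raises(InvalidInputError):
            m.threshold_ratio(-100.0, 0.0)


class TestHysteresis:
    def _ramp_trace(self, p_open, p_close, peak=-80.0):
        """Synthetic triangle sweep opening at p_open, closing at p_close."""
        rate = 1000.0
        protocol = m.build_protocol("triangle", peak, 3.0, rate, lead=1.0)
        p = protocol.pressure
        t = protocol.time
        i_peak = int(np.argmin(p))
        current = np.zeros(len(p))
        i_open = np.argmax(p[:i_peak] <= p_open)
        after = np.flatnonzero(p[i_peak:] >= p_close) + i_peak
        i_close = after[0]
        current[i_open:i_close] = 10.0
        trace = m.RecordingTrace(time=t, current=current, pressure=p,
                                 sampling_rate=rate, voltage=40.0)
        return trace

    @pytest.mark.parametrize("p_open, p_close, expected", [
        (-34.0, -14.0, 14.0 / 34.0),   # soft-membrane thresholds
        (-51.0, -64.0, 64.0 / 51.0),   # reversed hysteresis
        (-40.0, -40.0, 1.0),
    ])
    def test_ratio_arithmetic(self, p_open, p_close, expected):
        trace = self._ramp_trace(p_open, p_close)
        th = m.hysteresis(trace, m.idealize(trace))
        assert th.hysteresis_ratio == pytest.approx(expected, abs=0.02)
        assert not th.stuck_open

    def test_stuck_open_flag(self):
        protocol = m.build_protocol("triangle", -80.0, 3.0, 1000.0, lead=1.0)
        current = np.where(protocol.pressure <= -40.0, 10.0, 0.0)
        # never closes: stays open to the very end of the sweep
        i_open = int(np.argmax(protocol.pressure <= -40.0))
        current[i_open:] = 10.0
        trace = m.RecordingTrace(
            time=protocol.time, current=current, pressure=protocol.pressure,
            sampling_rate=1000.0, voltage=100.0)
        th = m.hysteresis(trace, m.idealize(trace))
        assert th.stuck_open
        assert th.hysteresis_ratio == 0.0

    def test_voltage_curve_flat_without_coupling(self, simulate_sweep,
                                                 nonvolt_mscCG):
        traces = []
        for v in (20.0, 60.0):
            for seed in range(3):
                trace, _ = simulate_sweep([nonvolt_mscCG], seed=40 + seed,
                                          peak=-150, duration=12.0,
                                          sampling_rate=2000.0, voltage=v)
                traces.append(trace)
        curve = m.hysteresis_voltage_curve(traces)
        ratios = [pt.mean_ratio for pt in curve]
        assert abs(ratios[0] - ratios[1]) < 0.15

    def test_voltage_curve_decreasing_with_coupling(self, simulate_sweep):
        traces = []
        for v in (20.0, 60.0, 100.0):
            for seed in range(3):
                trace, _ = simulate_sweep("mscCG", seed=60 + seed,
                                          peak=-150, duration=12.0,
                                          sampling_rate=2000.0, voltage=v)
                traces.append(trace)
        curve = m.hysteresis_voltage_curve(traces)
        assert [pt.voltage for pt in curve] == [20.0, 60.0, 100.0]
        assert curve[0].mean_ratio > curve[1].mean_ratio > curve[2].mean_ratio
        assert curve[2].n_stuck == curve[2].n  # fully stuck at +100 mV

    def test_empty_input(self):
        with pytest.raises(InvalidInputError):
            m.hysteresis_voltage_curve([])


class TestRectification:
    def test_exact_slope_lines(self):
        pts = [(v, 0.286 * v) for v in (20, 40, 60)] + \
              [(v, 0.095 * v) for v in (-20, -40, -60)]
        res = m.iv_rectification(pts)
        assert res.g_pos_pS == pytest.approx(286.0, rel=1e-9)
        assert res.g_neg_pS == pytest.approx(95.0, rel=1e-9)
        assert res.reduction == pytest.approx(0.668, abs=5e-4)

    def test_symmetric_line_no_reduction(self):
        pts = [(v, 0.3 * v) for v in (-60, -30, 30, 60)]
        res = m.iv_rectification(pts)
        assert res.g_pos_pS == pytest.approx(res.g_neg_pS)
        assert res.reduction == pytest.approx(0.0, abs=1e-12)

    def test_one_sided_insufficient(self):
        with pytest.raises(InsufficientDataError):
            m.iv_rectification([(30, 9.0), (60, 18.0), (-30, -3.0)])
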