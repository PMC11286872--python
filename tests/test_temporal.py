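"""Temporal cascade: pulse trains, leaky integrators, refractory attenuation,
slow integration and compression."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortisim.temporal import (PulseTrain, ResponseTrace, SpikeEvents,
                               TemporalParams, apply_refractory,
                               build_pulse_train, compress,
                               extract_spike_strengths, gamma_kernel,
                               integrate_stage1, max_r2_unit,
                               refractory_factor, simulate_temporal,
                               slow_integrate, stage1_closed_form)

TAU1 = 0.3


class TestPulseTrain:
    @pytest.mark.parametrize("f,dur,n", [(50, 0.5, 25), (75, 0.05, 3),
                                         (10, 0.95, 9)])
    def test_pulse_count(self, f, dur, n):
        tr = PulseTrain(amplitude=1, pulse_width=0.25, frequency=f,
                        train_duration=dur)
        assert tr.n_pulses == n
        wf = build_pulse_train(tr)
        # count positive-phase onsets in the sampled waveform
        pos = (wf.value > 0).astype(int)
        assert np.sum(np.diff(pos) == 1) == n

    def test_charge_per_phase(self):
        tr = PulseTrain(amplitude=3, pulse_width=0.25, frequency=50,
                        train_duration=0.5)
        assert tr.charge_per_phase == pytest.approx(0.75)

    def test_period_too_short_rejected(self):
        with pytest.raises(ValueError, match="period too short"):
            PulseTrain(amplitude=1, pulse_width=3.0, frequency=200,
                       train_duration=0.5)

    @given(amp=st.floats(0.1, 10), pw=st.floats(0.11, 2.0),
           f=st.floats(5, 150), dur=st.floats(0.02, 0.3))
    @settings(max_examples=25, deadline=None)
    def test_charge_balance(self, amp, pw, f, dur):
        if 2 * pw > 1000.0 / f:
            return
        tr = PulseTrain(amplitude=amp, pulse_width=pw, frequency=f,
                        train_duration=dur)
        wf = build_pulse_train(tr)
        assert abs(np.sum(wf.value) * wf.dt) < 1e-9 * amp


class TestStage1:
    def test_constant_input_closed_form(self):
        # R1(tau1) = A*tau1*(1 - 1/e) for constant input from t=0
        t = np.arange(0, 5.0, 0.001)
        wf = ResponseTrace(t, np.ones_like(t))
        r1 = integrate_stage1(wf, TAU1)
        assert r1.at(TAU1) == pytest.approx(TAU1 * (1 - math.e ** -1),
                                            rel=1e-6)
        # asymptote A*tau1
        assert r1.value[-1] == pytest.approx(TAU1, rel=1e-3)

    def test_zero_input_zero_output(self):
        t = np.arange(0, 10, 0.01)
        r1 = integrate_stage1(ResponseTrace(t, np.zeros_like(t)), TAU1)
        assert np.all(r1.value == 0)

    def test_matches_piecewise_oracle(self, rng):
        """Numeric integrator vs analytic per-phase recursion, 20 trains."""
        for _ in range(20):
            amp = rng.uniform(0.5, 10)
            pw = rng.uniform(0.11, 2.0)
            f = rng.uniform(5, 150)
            if 2 * pw > 1000 / f:
                continue
            tr = PulseTrain(amplitude=amp, pulse_width=pw, frequency=f,
                            train_duration=rng.uniform(0.02, 0.1))
            wf = build_pulse_train(tr)
            r1 = integrate_stage1(wf, TAU1)
            idx = rng.integers(0, wf.time.size, 30)
            exact = stage1_closed_form(tr, TAU1, wf.time[idx])
            scale = amp * TAU1 * (1 - math.exp(-pw / TAU1))
            assert np.abs(r1.value[idx] - exact).max() / scale < 1e-3


class TestSpikeEvents:
    def test_single_pulse_strength(self):
        tr = PulseTrain(amplitude=1, pulse_width=0.25, frequency=50,
                        train_duration=0.02)
        r1 = integrate_stage1(build_pulse_train(tr), TAU1)
        ev = extract_spike_strengths(r1, tr, tau1=TAU1)
        expect = TAU1 * (1 - math.exp(-0.25 / TAU1)) ** 2
        assert ev.strengths[0] == pytest.approx(expect, rel=1e-9)
        # event at offset of the positive (second) phase
        assert ev.times[0] == pytest.approx(2 * 0.25 / 1000.0)

    def test_anodic_first_event_at_first_phase(self):
        tr = PulseTrain(amplitude=1, pulse_width=0.25, frequency=50,
                        train_duration=0.02, polarity="anodic-first")
        r1 = integrate_stage1(build_pulse_train(tr), TAU1)
        ev = extract_spike_strengths(r1, tr, tau1=TAU1)
        assert ev.times[0] == pytest.approx(0.25 / 1000.0)
        assert ev.strengths[0] == pytest.approx(
            TAU1 * (1 - math.exp(-0.25 / TAU1)), rel=1e-9)

    def test_zero_amplitude_zero_strengths(self):
        tr = PulseTrain(amplitude=0, pulse_width=0.25, frequency=50,
                        train_duration=0.1)
        r1 = integrate_stage1(build_pulse_train(tr), TAU1)
        ev = extract_spike_strengths(r1, tr, tau1=TAU1)
        assert np.all(ev.strengths == 0)


class TestRefractory:
    def test_worked_example(self):
        # 50 Hz interval with rate 50/s and 1 ms offset -> 0.6501
        assert refractory_factor(1 / 50, 50.0, 0.001) == pytest.approx(
            0.6501, abs=5e-5)

    def test_limits(self):
        assert refractory_factor(np.inf, 50.0, 0.001) == 1.0
        assert refractory_factor(0.0, 50.0, 0.001) == pytest.approx(
            1 - math.exp(-0.05))

    def test_first_event_unattenuated(self):
        ev = SpikeEvents(times=np.array([0.0, 0.02]),
                         strengths=np.array([1.0, 1.0]))
        out = apply_refractory(ev, 50.0, 0.001)
        assert out.strengths[0] == 1.0
        assert out.strengths[1] == pytest.approx(0.6501, abs=5e-5)

    @given(d1=st.floats(1e-4, 0.2), d2=st.floats(1e-4, 0.2))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_and_bounded(self, d1, d2):
        f1 = refractory_factor(d1, 50.0, 0.001)
        f2 = refractory_factor(d2, 50.0, 0.001)
        assert 0 < f1 <= 1
        if d1 < d2:
            assert f1 < f2


class TestSlowStage:
    def test_kernel_unit_mass(self):
        t_ms, g = gamma_kernel(150.0, 3, 1.0)
        assert np.trapezoid(g, t_ms / 1000.0) == pytest.approx(1.0, abs=1e-3)

    def test_impulse_peaks_at_gamma_mode(self):
        ev = SpikeEvents(times=np.array([0.0]), strengths=np.array([1.0]))
        r2 = slow_integrate(ev, 150.0, 3, 1.0)
        assert r2.time[np.argmax(r2.value)] == pytest.approx(2 * 150.0,
                                                             abs=2.0)

    def test_linearity(self):
        times = np.array([0.0, 0.02, 0.04])
        s = np.array([1.0, 0.5, 2.0])
        r2a = slow_integrate(SpikeEvents(times, s), 150.0, 3, 1.0)
        r2b = slow_integrate(SpikeEvents(times, 2 * s), 150.0, 3, 1.0)
        np.testing.assert_allclose(r2b.value, 2 * r2a.value, rtol=1e-12)


class TestCompress:
    def test_zero_and_saturation(self):
        assert compress(np.array(0.0), 0.57, 15.6, 10.0) == 0
        assert compress(np.array(1e9), 0.57, 15.6, 10.0) == pytest.approx(10.0)

    def test_small_signal_slope(self):
        eps = 1e-6
        out = compress(np.array(eps), 0.57, 15.6, 10.0)
        assert out / eps == pytest.approx(10.0 * 0.57 / 15.6, rel=1e-4)


class TestSimulate:
    def test_zero_amplitude(self, params):
        tr = PulseTrain(amplitude=0, pulse_width=0.25, frequency=50,
                        train_duration=0.1)
        res = simulate_temporal(tr, params)
        assert res.max_brightness == 0 and res.max_r2 == 0

    def test_monotone_in_amplitude(self, params):
        tr = PulseTrain(amplitude=1, pulse_width=0.25, frequency=50,
                        train_duration=0.2)
        vals = [simulate_temporal(replace(tr, amplitude=a), params).max_r2
                for a in np.linspace(0.5, 10, 8)]
        assert np.all(np.diff(vals) > 0)

    def test_homogeneous_degree_one(self, params):
        tr = PulseTrain(amplitude=2.0, pulse_width=0.5, frequency=75,
                        train_duration=0.1)
        r_a = simulate_temporal(tr, params).max_r2
        r_3a = simulate_temporal(replace(tr, amplitude=6.0), params).max_r2
        assert r_3a == pytest.approx(3 * r_a, rel=1e-12)
        assert r_a == pytest.approx(2 * max_r2_unit(tr, params), rel=1e-12)

    def test_brightness_rises_then_decays_after_offset(self, params):
        # classic demonstration train: 2 ms phases, 75 Hz, 50 ms
        tr = PulseTrain(amplitude=20, pulse_width=2.0, frequency=75,
                        train_duration=0.05)
        res = simulate_temporal(tr, params)
        b = res.brightness
        ipk = int(np.argmax(b.value))
        assert b.time[ipk] > 50.0            # peak after train offset
        assert b.value[-1] < 0.05 * b.value[ipk]   # decays away
        # rises monotonically-ish into the peak
        assert b.value[ipk] > b.value[ipk // 2] > 0
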