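"""Unit dynamics: leaky integrators, adaptation, rectification, delays."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beeav.core import (AdaptiveLINState, ConfigurationError, DelayLine, LINState,
                        RectifierMode, adaptive_lin_update, lin_update, rectify,
                        step_adaptive_lin, step_delay_line, step_lin)

DT = 0.1  # ms


class TestLIN:
    def test_single_euler_step(self):
        s = step_lin(LINState(a=0.0, tau=1.0), input_sum=1.0, dt=DT)
        assert s.a == pytest.approx(0.1)

    def test_converges_to_constant_input(self):
        s = LINState(a=0.0, tau=5.0)
        for _ in range(int(100 / DT)):  # 100 ms >> tau
            s = step_lin(s, 0.7, DT)
        assert s.a == pytest.approx(0.7, abs=1e-6)

    def test_free_decay_matches_exponential(self):
        # a(t) = e^(-t/tau): after one time constant the stepped solution
        # must sit within Euler error of 1/e
        s = LINState(a=1.0, tau=5.0)
        for _ in range(int(5.0 / DT)):
            s = step_lin(s, 0.0, DT)
        assert abs(s.a - math.exp(-1.0)) < 0.01

    def test_rejects_bad_timesteps(self):
        with pytest.raises(ConfigurationError):
            step_lin(LINState(tau=5.0), 0.0, dt=0.0)
        with pytest.raises(ConfigurationError):
            LINState(tau=-1.0)
        with pytest.raises(ConfigurationError):
            # dt > tau would make explicit stepping unstable
            step_lin(LINState(tau=0.05), 0.0, dt=DT)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-1, 1), min_size=5, max_size=40),
           st.lists(st.floats(-1, 1), min_size=5, max_size=40),
           st.floats(-2, 2), st.floats(-2, 2))
    def test_linearity(self, x1, x2, alpha, beta):
        """The LIN is a linear filter: response to a*x1 + b*x2 superposes."""
        n = min(len(x1), len(x2))
        x1, x2 = np.array(x1[:n]), np.array(x2[:n])

        def run(x):
            a = 0.0
            out = []
            for xi in x:
                a = lin_update(a, xi, tau=5.0, dt=DT)
                out.append(a)
            return np.array(out)

        combined = run(alpha * x1 + beta * x2)
        superposed = alpha * run(x1) + beta * run(x2)
        assert np.allclose(combined, superposed, atol=1e-10)

    def test_halving_dt_changes_trajectory_below_one_percent(self):
        x = lambda t: 0.5 + 0.5 * math.sin(2 * math.pi * 10 * t / 1000.0)

        def final(dt):
            a = 0.0
            for i in range(int(2000.0 / dt)):  # 2 s
                a = lin_update(a, x(i * dt), tau=5.0, dt=dt)
            return a

        a1, a2 = final(DT), final(DT / 2)
        assert abs(a1 - a2) / abs(a2) < 0.01

    def test_tau_multiplies_switch_changes_rate(self):
        fast = lin_update(0.0, 1.0, tau=5.0, dt=DT, tau_multiplies=True)
        slow = lin_update(0.0, 1.0, tau=5.0, dt=DT)
        assert fast == pytest.approx(0.5) and slow == pytest.approx(0.02)


class TestAdaptiveLIN:
    def test_steady_state_is_pure_change_detector(self):
        """Held input: adaptation absorbs it, output returns to zero."""
        s = AdaptiveLINState()
        for _ in range(int(2000 / DT)):  # 2 s at x = 0.5
            s = step_adaptive_lin(s, 0.5, DT)
        assert s.alpha == pytest.approx(0.5, abs=1e-6)
        assert abs(s.a_pr) < 1e-6

    def test_step_transient_signs(self):
        s = AdaptiveLINState()
        s = step_adaptive_lin(s, 1.0, DT)  # onset: positive transient
        assert s.a_pr > 0
        # settle at 1, then drop to 0: negative transient
        for _ in range(int(2000 / DT)):
            s = step_adaptive_lin(s, 1.0, DT)
        s = step_adaptive_lin(s, 0.0, DT)
        assert s.a_pr < s.alpha * 0  # strictly negative

    def test_zero_dc_gain(self):
        """Time-average of the output under constant drive vanishes."""
        a, alpha = 0.0, 0.0
        acc = n = 0
        for i in range(int(5000 / DT)):  # 5 s
            a, alpha = adaptive_lin_update(a, alpha, 0.8, 8.0, 15.0, DT)
            if i >= int(4000 / DT):
                acc += a
                n += 1
        assert abs(acc / n) < 1e-3

    def test_step_response_peak_matches_dense_reference(self):
        """Coarse-step peak value and time agree with a dt=0.001 ms solution."""
        def peak(dt):
            a = alpha = 0.0
            best, t_best = -1.0, 0.0
            for i in range(int(60.0 / dt)):  # 60 ms covers the transient
                a, alpha = adaptive_lin_update(a, alpha, 1.0, 8.0, 15.0, dt)
                if a > best:
                    best, t_best = a, (i + 1) * dt
            return best, t_best

        coarse, dense = peak(0.1), peak(0.001)
        assert coarse[0] == pytest.approx(dense[0], rel=0.02)
        assert coarse[1] == pytest.approx(dense[1], rel=0.02)


class TestRectify:
    @pytest.mark.parametrize("a,mode,expected", [
        (-0.3, RectifierMode.OFFSET_ONLY, 0.3),
        (0.3, RectifierMode.OFFSET_ONLY, 0.0),
        (0.3, RectifierMode.ONSET_ONLY, 0.3),
        (-0.3, RectifierMode.ONSET_ONLY, 0.0),
        (-0.3, RectifierMode.FULL, 0.3),
        (-0.3, RectifierMode.NONE, -0.3),
    ])
    def test_modes(self, a, mode, expected):
        assert rectify(a, mode) == pytest.approx(expected)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            rectify(0.1, "half")

    def test_array_input(self):
        out = rectify(np.array([-1.0, 0.5]), RectifierMode.OFFSET_ONLY)
        assert np.allclose(out, [1.0, 0.0])


class TestDelayLine:
    def test_impulse_emerges_after_delay(self):
        line = DelayLine(d=5.0, dt=DT)
        outs = [step_delay_line(line, 1.0 if i == 0 else 0.0) for i in range(80)]
        assert outs[:50] == [0.0] * 50
        assert outs[50] == 1.0
        assert all(o == 0.0 for o in outs[51:])

    def test_zero_delay_is_identity(self):
        line = DelayLine(d=0.0, dt=DT)
        assert line.step(0.7) == 0.7

    def test_sinusoid_shift_is_sample_exact(self):
        d = 15.0
        line = DelayLine(d=d, dt=DT)
        f = 20.0  # Hz
        n = int(200 / DT)
        t = np.arange(n) * DT
        x = np.sin(2 * np.pi * f * t / 1000.0)
        y = np.array([line.step(xi) for xi in x])
        shifted = np.sin(2 * np.pi * f * (t - d) / 1000.0)
        steps = int(d / DT)
        assert np.allclose(y[steps:], shifted[steps:], atol=1e-12)

    def test_non_multiple_delay_rounds_with_warning(self):
        with pytest.warns(UserWarning):
            line = DelayLine(d=0.25, dt=DT)
        assert line.n_steps == 2
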