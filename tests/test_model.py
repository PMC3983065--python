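"""Threshold dynamics: steady-state curve, ODE integration, spike prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from threshfit import (ThresholdModelParams, VoltageTrace,
                       integrate_threshold, predict_spikes,
                       steady_state_threshold)
from threshfit.model import ParameterError


class TestParams:
    def test_rejects_invalid(self):
        with pytest.raises(ParameterError):
            ThresholdModelParams(tau_theta=-1, V_i=-59, theta_offset=-61,
                                 alpha=0, beta=1, k_a=7)
        with pytest.raises(ParameterError):
            ThresholdModelParams(tau_theta=1, V_i=-59, theta_offset=-61,
                                 alpha=0, beta=1, k_a=0)
        with pytest.raises(ParameterError):
            ThresholdModelParams(tau_theta=1, V_i=-59, theta_offset=-61,
                                 alpha=1.0, beta=0.5, k_a=7)

    def test_json_round_trip(self, rectified_params):
        restored = ThresholdModelParams.from_json(rectified_params.to_json())
        assert restored == rectified_params

    def test_json_keys_carry_units(self, rectified_params):
        d = rectified_params.to_dict()
        assert set(d) == {"tau_theta_ms", "V_i_mV", "theta_offset_mV",
                          "alpha", "beta", "k_a_mV"}


class TestSteadyState:
    def test_constant_when_both_slopes_zero(self):
        p = ThresholdModelParams(tau_theta=1, V_i=-59, theta_offset=-61,
                                 alpha=0, beta=0, k_a=7)
        V = np.linspace(-100, 0, 50)
        assert np.allclose(steady_state_threshold(p, V), -61.0)

    def test_value_at_knee(self):
        # softplus(0) = ln 2, so theta_inf(V_i) = offset + (b-a)*k_a*ln 2
        p = ThresholdModelParams(tau_theta=1, V_i=-59, theta_offset=-61,
                                 alpha=0, beta=1, k_a=7)
        expected = -61 + 7 * np.log(2)
        assert steady_state_threshold(p, -59.0) == pytest.approx(expected, abs=1e-12)

    def test_asymptotic_slopes(self):
        p = ThresholdModelParams(tau_theta=1, V_i=-59, theta_offset=-61,
                                 alpha=0, beta=1, k_a=7)
        eps = 1e-4
        # far above the knee the slope approaches beta = 1
        v_hi = p.V_i + 10 * p.k_a
        slope_hi = (steady_state_threshold(p, v_hi + eps)
                    - steady_state_threshold(p, v_hi)) / eps
        assert slope_hi == pytest.approx(1.0, abs=1e-3)
        v_lo = p.V_i - 10 * p.k_a
        slope_lo = (steady_state_threshold(p, v_lo + eps)
                    - steady_state_threshold(p, v_lo)) / eps
        assert slope_lo == pytest.approx(0.0, abs=1e-3)

    def test_no_overflow_far_from_knee(self, rectified_params):
        out = steady_state_threshold(rectified_params, np.array([-1e4, 1e4]))
        assert np.all(np.isfinite(out))

    @given(v_shift=st.floats(-20, 20), alpha=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_v_for_nonnegative_slopes(self, v_shift, alpha):
        p = ThresholdModelParams(tau_theta=1, V_i=-59 + v_shift,
                                 theta_offset=-61, alpha=alpha,
                                 beta=alpha + 0.5, k_a=5)
        V = np.linspace(-90, -30, 200)
        theta = steady_state_threshold(p, V)
        assert np.all(np.diff(theta) >= -1e-12)

    def test_rejects_nonfinite_voltage(self, rectified_params):
        with pytest.raises(ParameterError):
            steady_state_threshold(rectified_params, np.array([np.nan]))


class TestIntegration:
    def test_fixed_point_for_constant_voltage(self, rectified_params):
        v0 = -60.0
        n = int(10 * rectified_params.tau_theta / 0.0238)
        trace = VoltageTrace(np.full(n, v0), dt=0.0238)
        theta = integrate_threshold(rectified_params, trace)
        target = steady_state_threshold(rectified_params, v0)
        assert np.max(np.abs(theta.samples - target)) < 1e-12

    def test_closed_form_relaxation(self, rectified_params):
        v0, offset0 = -60.0, 5.0
        dt = 0.0238
        n = 4000
        trace = VoltageTrace(np.full(n, v0), dt=dt)
        target = steady_state_threshold(rectified_params, v0)
        theta = integrate_threshold(rectified_params, trace,
                                    theta0=target + offset0)
        t = np.arange(n) * dt
        expected = target + offset0 * np.exp(-t / rectified_params.tau_theta)
        assert np.max(np.abs(theta.samples - expected)) < 1e-9

    def test_matches_fine_euler_on_ou_trace(self, rectified_params, ou_trace):
        """Exact-update integration vs 20x-finer explicit Euler oracle."""
        theta = integrate_threshold(rectified_params, ou_trace)
        fine = _euler_oracle(rectified_params, ou_trace, refine=20)
        assert np.max(np.abs(theta.samples - fine)) <= 0.01

    def test_small_tau_tracks_steady_state(self, ou_trace):
        p = ThresholdModelParams(tau_theta=1e-4, V_i=-59, theta_offset=-57,
                                 alpha=0, beta=1, k_a=3)
        with pytest.warns(UserWarning):
            theta = integrate_threshold(p, ou_trace)
        target = steady_state_threshold(p, ou_trace.samples)
        # one-sample lag at most; compare shifted
        assert np.max(np.abs(theta.samples[1:] - target[:-1])) < 1e-6

    def test_monotone_in_voltage(self, rectified_params, ou_trace):
        hi = VoltageTrace(ou_trace.samples + 2.0, dt=ou_trace.dt)
        th_lo = integrate_threshold(rectified_params, ou_trace)
        th_hi = integrate_threshold(rectified_params, hi)
        assert np.all(th_hi.samples >= th_lo.samples - 1e-12)


def _euler_oracle(params, trace, refine=20):
    """Explicit-Euler integration at a refine-x finer step, subsampled back."""
    dt_f = trace.dt / refine
    s = steady_state_threshold(params, trace.samples)
    theta = np.empty(trace.samples.size)
    th = s[0]
    for i in range(trace.samples.size):
        theta[i] = th
        for _ in range(refine):
            th += dt_f / params.tau_theta * (s[i] - th)
    return theta


class TestPredictSpikes:
    def test_no_spikes_when_trace_below_steady_state(self, rectified_params):
        rng = np.random.default_rng(3)
        v = -70 + 2 * rng.standard_normal(20000)  # theta_inf(-70) ~ -56.9
        trace = VoltageTrace(v, dt=0.0238)
        train, _ = predict_spikes(rectified_params, trace)
        assert len(train) == 0

    def test_step_triggers_immediate_spike(self):
        # voltage jump from -70 to -50 lands while theta is still near -61
        p = ThresholdModelParams(tau_theta=1.0, V_i=-59, theta_offset=-61,
                                 alpha=0, beta=1, k_a=1e-6)
        dt = 0.0238
        n_pre = 2000
        v = np.concatenate([np.full(n_pre, -70.0), np.full(2000, -50.0)])
        train, theta = predict_spikes(p, VoltageTrace(v, dt=dt))
        assert len(train) >= 1
        assert train.times[0] == pytest.approx(n_pre * dt, abs=dt / 2)
        # afterwards theta relaxes toward theta_inf(-50) = -61 + 9 = -52
        assert theta.samples[-1] == pytest.approx(-52.0, abs=1e-3)

    def test_slow_ramp_never_crosses(self):
        """A slowly depolarizing neuron does not spike: the threshold rises along.

        Holds whenever the steady-state curve stays above the diagonal
        (theta_offset > V_i) and the ramp is slow against tau_theta.
        """
        p = ThresholdModelParams(tau_theta=0.26, V_i=-59, theta_offset=-57,
                                 alpha=0, beta=1, k_a=1e-6)
        dt = 0.0238
        t = np.arange(int(200 / dt)) * dt
        v = -70 + 0.1 * t  # 0.1 mV/ms ramp over 200 ms
        train, theta = predict_spikes(p, VoltageTrace(v, dt=dt))
        assert len(train) == 0
        assert np.all(theta.samples - v > 0)

    def test_refractory_enforced(self, constant_params):
        # constant suprathreshold voltage: spikes at exactly the refractory cadence
        v = np.full(2000, -50.0)
        train, _ = predict_spikes(constant_params, VoltageTrace(v, dt=0.0238),
                                  refractory_ms=0.5)
        isis = np.diff(train.times)
        assert len(train) > 10
        assert np.all(isis >= 0.5 - 1e-9)

    def test_constant_threshold_reduces_to_level_crossing(self, constant_params):
        rng = np.random.default_rng(8)
        v = -60 + 6 * rng.standard_normal(50000)
        trace = VoltageTrace(v, dt=0.0238)
        train, theta = predict_spikes(constant_params, trace)
        assert np.allclose(theta.samples, -55.0)
        # every predicted spike sits on a sample with V >= -55
        idx = np.round(train.times / trace.dt).astype(int)
        assert np.all(v[idx] >= -55.0)
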