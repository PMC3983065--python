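"""Compiled inner loops.

The fitting objective evaluates the threshold model thousands of times on
traces of ~10^6 samples, so the steady-state curve, the exact exponential
update and the crossing detector are fused into a single compiled pass.
`threshfit.model` holds the plain numpy/scipy reference implementation;
the two are asserted equivalent in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["predict_spike_indices", "simulate_eif"]


@njit(cache=True)
def _theta_inf(v, V_i, theta_offset, alpha, beta, k_a):
    x = (v - V_i) / k_a
    if x > 0.0:
        sp = x + math.log1p(math.exp(-x))
    else:
        sp = math.log1p(math.exp(x))
    return theta_offset + alpha * (v - V_i) + (beta - alpha) * k_a * sp


@njit(cache=True, fastmath=True)
def predict_spike_indices(V, dt, tau_theta, V_i, theta_offset, alpha, beta,
                          k_a, refractory_ms):
    """Fused threshold integration + crossing detection.

    Returns the sample indices of predicted spikes.  Semantics match
    `model.predict_spikes`: theta starts at theta_inf(V[0]), advances by the
    exact exponential update with V held constant per interval, and a spike
    is emitted at any sample with V >= theta at least ``refractory_ms``
    after the previous one.  The threshold is never reset.
    """
    n = V.size
    a = math.exp(-dt / tau_theta)
    theta = _theta_inf(V[0], V_i, theta_offset, alpha, beta, k_a)
    out = np.empty(n, dtype=np.int64)
    m = 0
    last = -1e30
    for i in range(n):
        if V[i] >= theta:
            if (i - last) * dt >= refractory_ms - 1e-12:
                out[m] = i
                m += 1
                last = i
        s = _theta_inf(V[i], V_i, theta_offset, alpha, beta, k_a)
        theta = s + (theta - s) * a
    return out[:m]


@njit(cache=True, fastmath=True)
def predict_spike_indices_tabled(V, dt, tau_theta, refractory_ms,
                                 v0, inv_dv, table):
    """As `predict_spike_indices`, with theta_inf given as a lookup table.

    ``table[k]`` holds theta_inf at voltage ``v0 + k/inv_dv``; lookups are
    linearly interpolated and clamped at the table edges (the table is
    built to cover the trace's full voltage range, so clamping never
    triggers in practice).  Avoids per-sample transcendentals in the
    optimizer's inner loop.
    """
    n = V.size
    m = table.size
    a = math.exp(-dt / tau_theta)

    x = (V[0] - v0) * inv_dv
    if x <= 0.0:
        theta = table[0]
    elif x >= m - 1:
        theta = table[m - 1]
    else:
        k = int(x)
        theta = table[k] + (table[k + 1] - table[k]) * (x - k)
    out = np.empty(n, dtype=np.int64)
    cnt = 0
    last = -1e30
    for i in range(n):
        if V[i] >= theta:
            if (i - last) * dt >= refractory_ms - 1e-12:
                out[cnt] = i
                cnt += 1
                last = i
        x = (V[i] - v0) * inv_dv
        if x <= 0.0:
            s = table[0]
        elif x >= m - 1:
            s = table[m - 1]
        else:
            k = int(x)
            s = table[k] + (table[k + 1] - table[k]) * (x - k)
        theta = s + (theta - s) * a
    return out[:cnt]


@njit(cache=True)
def simulate_eif(I, dt, tau_m, E_L, Delta_T, R, V_reset, refractory_ms,
                 V_detect, tau_theta, V_i, theta_offset, alpha, beta, k_a,
                 waveform_ms, waveform_peak_mV, jitter):
    """Exponential integrate-and-fire neuron with an explicit adaptive threshold.

    Explicit Euler on the voltage, exact exponential update on the
    threshold.  When the voltage reaches ``V_detect`` (or, in the
    ``Delta_T == 0`` leaky limit, the threshold itself) a spike is
    registered; a stylized triangular upstroke to ``waveform_peak_mV`` over
    ``waveform_ms`` is written into the *output* trace, then the voltage is
    held at ``V_reset`` for the remaining refractory period.  The hidden
    ground-truth threshold integrates the clamped (reset-held) voltage
    during the waveform and refractory, never the cosmetic upstroke.

    ``jitter`` is a per-sample hidden perturbation of the spiking
    criterion (mV): the sodium-activation term and the leaky-limit spike
    condition use ``theta + jitter`` while the logged ground truth stays
    the nominal threshold.  Pass a single zero for a deterministic neuron.

    Returns (V_out, theta_true, spike_indices).
    """
    n = I.size
    has_jitter = jitter.size == n
    a = math.exp(-dt / tau_theta)
    V = np.empty(n)
    theta = np.empty(n)
    spikes = np.empty(n, dtype=np.int64)
    nspk = 0
    v = E_L
    th = _theta_inf(E_L, V_i, theta_offset, alpha, beta, k_a)
    wf_steps = max(1, int(round(waveform_ms / dt)))
    refr_steps = max(wf_steps, int(round(refractory_ms / dt)))
    i = 0
    while i < n:
        V[i] = v
        theta[i] = th
        th_eff = th + (jitter[i] if has_jitter else 0.0)
        spiking = (v >= V_detect) or (Delta_T == 0.0 and v >= th_eff)
        if spiking:
            spikes[nspk] = i
            nspk += 1
            # Stylized waveform on the output trace; theta sees V_reset.
            # When the crossing value itself is subthreshold-looking
            # (leaky limit: detection at the threshold), the crossing
            # sample is preserved and the ramp starts one sample later;
            # when the voltage has already diverged, the ramp starts at
            # the detection sample from the last stored subthreshold
            # value, so the upstroke stays monotone for onset detection.
            if v < waveform_peak_mV:
                start_v = v
                ramp_from = 1
                V[i] = v
            else:
                start_v = V[i - 1] if i > 0 else V_reset
                if start_v >= waveform_peak_mV:
                    start_v = V_reset
                ramp_from = 0
            for j in range(ramp_from, refr_steps):
                if i + j >= n:
                    break
                k = j - ramp_from
                if k < wf_steps:
                    V[i + j] = (start_v + (waveform_peak_mV - start_v)
                                * (k + 1) / wf_steps)
                else:
                    V[i + j] = V_reset
            for j in range(refr_steps):
                if i + j >= n:
                    break
                s = _theta_inf(V_reset, V_i, theta_offset, alpha, beta, k_a)
                th = s + (th - s) * a
                theta[i + j] = th
            v = V_reset
            i += refr_steps
            continue
        # Euler step; exponent clipped so one oversized step cannot overflow
        if Delta_T > 0.0:
            x = (v - th_eff) / Delta_T
            if x > 30.0:
                x = 30.0
            drive = Delta_T * math.exp(x)
        else:
            drive = 0.0
        dv = ((E_L - v) + drive + R * I[i]) / tau_m * dt
        s = _theta_inf(v, V_i, theta_offset, alpha, beta, k_a)
        th = s + (th - s) * a
        v = v + dv
        if not math.isfinite(v):
            raise ValueError("voltage diverged outside a spike")
        i += 1
    return V, theta, spikes[:nspk]
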