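import numpy as np
import pytest

from threshfit import (EIFParams, OUParams, ThresholdModelParams,
                       VoltageTrace, ou_current, simulate_eif_adaptive)

DT_42KHZ = 1000.0 / 42000.0


@pytest.fixture
def rectified_params() -> ThresholdModelParams:
    """A rectified-linear adaptive threshold: flat below the knee, slope 1 above."""
    return ThresholdModelParams(tau_theta=3.0, V_i=-59.0, theta_offset=-57.0,
                                alpha=0.0, beta=1.0, k_a=3.0)


@pytest.fixture
def constant_params() -> ThresholdModelParams:
    """A fixed threshold at -55 mV (alpha = beta = 0)."""
    return ThresholdModelParams(tau_theta=3.0, V_i=-59.0, theta_offset=-55.0,
                                alpha=0.0, beta=0.0, k_a=7.0)


@pytest.fixture
def ou_trace() -> VoltageTrace:
    """A 1 s OU-like voltage trace (colored noise around -65 mV)."""
    rng = np.random.default_rng(11)
    n = 42000
    dt = DT_42KHZ
    a = np.exp(-dt / 3.0)
    noise = rng.standard_normal(n) * 4.0 * np.sqrt(1 - a * a)
    v = np.empty(n)
    v[0] = -65.0
    for i in range(1, n):
        v[i] = -65.0 + (v[i - 1] + 65.0) * a + noise[i]
    return VoltageTrace(samples=v, dt=dt)


@pytest.fixture(scope="session")
def eif_fixture():
    """A short simulated EIF recording with known adaptive threshold.

    Uses sharp spike initiation (Delta_T = 0.5 mV), as somatic onsets in
    vivo are kink-like, with the standard fast-plus-envelope drive.
    """
    thr = ThresholdModelParams(tau_theta=3.0, V_i=-59.0, theta_offset=-57.0,
                               alpha=0.0, beta=1.0, k_a=3.0)
    I = ou_current(OUParams(duration=10000.0, seed=21))
    I = I + ou_current(OUParams(mean=0.0, sd=150.0, tau_I=50.0,
                                duration=10000.0, seed=5021))
    trace, theta, spikes = simulate_eif_adaptive(EIFParams(Delta_T=0.5),
                                                 thr, I)
    return {"params": thr, "trace": trace, "theta": theta, "spikes": spikes}
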