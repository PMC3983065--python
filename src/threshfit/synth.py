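"""Ground-truth data generation.

Simulated neurons with a *known* adaptive threshold serve as the benchmark
for the fitting procedure: an exponential integrate-and-fire (EIF) neuron

    τ_m dV/dt = (E_L − V) + Δ_T·exp((V − θ)/Δ_T) + R·I(t)

driven by an Ornstein–Uhlenbeck current, with θ(t) evolving by the same
first-order adaptive-threshold dynamics the fitting module estimates.  The
exponential sodium-activation term makes spike initiation sharp, so the
onset-detection machinery applies to simulated traces exactly as to
recordings.  Once the voltage diverges past a detection ceiling it is
reset to −70 mV and a 0.8 ms refractory period follows; a stylized spike
waveform is superimposed on the output trace so that peak/onset detection
code paths are exercised.

Default condition values: OU current with mean 40 pA, SD 120 pA and time
constant 3 ms; simulation at 42 kHz.  The scenario suite covers a constant
threshold, a rectified-linear adaptive threshold (τ_θ = 3 ms), a fully
linear one (τ_θ = 5 ms), a fast rectified one (τ_θ = 0.3 ms with 0.5 ms
input correlation time), and a grid of input currents (means 20–200 pA,
SDs 50–400 pA) screened for at least 20 spikes and a rate below 200 Hz.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .model import (SpikeTrain, ThresholdModelParams, ThresholdTrace,
                    VoltageTrace, ParameterError)

__all__ = [
    "EIFParams",
    "OUParams",
    "ou_current",
    "simulate_eif_adaptive",
    "make_fixture_suite",
    "make_psp_trace",
    "excise_spikes_to_reset",
    "SCENARIOS",
    "SCENARIO_EIF",
    "DEFAULT_DT_MS",
]

#: 42 kHz simulation rate.
DEFAULT_DT_MS = 1000.0 / 42000.0


@dataclass(frozen=True)
class EIFParams:
    """Exponential integrate-and-fire constants.

    Defaults produce firing rates of tens of Hz under an OU current with
    mean 40 pA and SD 120 pA.
    """

    tau_m: float = 5.0         # membrane time constant, ms
    E_L: float = -70.0         # leak reversal, mV
    Delta_T: float = 1.0       # spike-initiation sharpness, mV
    R: float = 100.0           # membrane resistance, MOhm (mV per nA)
    V_reset: float = -70.0     # post-spike reset, mV
    refractory: float = 0.8    # ms
    V_detect: float = 0.0      # numerical spike-detection ceiling, mV
    waveform_ms: float = 0.3   # stylized upstroke duration
    waveform_peak_mV: float = 10.0

    def __post_init__(self):
        if self.tau_m <= 0 or self.R <= 0 or self.Delta_T < 0:
            raise ParameterError("tau_m, R must be > 0 and Delta_T >= 0")


@dataclass(frozen=True)
class OUParams:
    """Ornstein–Uhlenbeck current parameters (pA, ms)."""

    mean: float = 40.0
    sd: float = 120.0
    tau_I: float = 3.0
    duration: float = 20000.0
    dt: float = DEFAULT_DT_MS
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0 or self.tau_I <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ParameterError("invalid OU parameters")


def ou_current(p: OUParams) -> np.ndarray:
    """Exact-discretization OU sample path (pA), starting at the mean.

    I[n+1] = μ + (I[n] − μ)·e^(−dt/τ) + σ·sqrt(1 − e^(−2dt/τ))·ξ_n,
    which has the exact stationary mean μ, SD σ and autocorrelation
    e^(−lag/τ) at any step size.
    """
    n = int(round(p.duration / p.dt))
    rng = np.random.default_rng(p.seed)
    a = math.exp(-p.dt / p.tau_I)
    noise_scale = p.sd * math.sqrt(1.0 - a * a)
    xi = rng.standard_normal(n - 1)
    I = np.empty(n)
    I[0] = p.mean
    # first-order recursion; the loop in compiled form is not needed at
    # fixture scale, scipy's lfilter handles it
    from scipy.signal import lfilter
    fluct = lfilter([0.0, noise_scale], [1.0, -a], np.concatenate(([0.0], xi)),
                    zi=np.array([0.0]))[0]
    I = p.mean + fluct
    return I


def simulate_eif_adaptive(
    eif: EIFParams,
    thr: ThresholdModelParams,
    I: np.ndarray,
    dt: float = DEFAULT_DT_MS,
    meta: dict | None = None,
    threshold_jitter: np.ndarray | None = None,
) -> tuple[VoltageTrace, ThresholdTrace, SpikeTrain]:
    """Simulate the EIF neuron with adaptive threshold under a current (pA).

    ``threshold_jitter``, if given, is a per-sample hidden perturbation of
    the spiking criterion (mV) emulating the intrinsic unpredictability of
    real recordings (channel noise, axonal influences); the returned
    ground-truth threshold trace is the nominal, noise-free threshold.

    Returns the voltage trace (stylized spike waveforms included), the
    hidden ground-truth threshold trace, and the true spike times (the
    detection samples).
    """
    I_nA = np.ascontiguousarray(I, dtype=float) * 1e-3  # pA -> nA; R in MOhm gives mV
    if threshold_jitter is None:
        jit = np.zeros(1)
    else:
        jit = np.ascontiguousarray(threshold_jitter, dtype=float)
        if jit.size != I_nA.size:
            raise ParameterError("threshold_jitter must match the current length")
    V, theta, spk = _kernels.simulate_eif(
        I_nA, dt, eif.tau_m, eif.E_L, eif.Delta_T, eif.R, eif.V_reset,
        eif.refractory, eif.V_detect, thr.tau_theta, thr.V_i,
        thr.theta_offset, thr.alpha, thr.beta, thr.k_a,
        eif.waveform_ms, eif.waveform_peak_mV, jit)
    trace = VoltageTrace(samples=V, dt=dt, meta=dict(meta or {}))
    ttrace = ThresholdTrace(samples=theta, dt=dt)
    train = SpikeTrain(times=spk.astype(float) * dt, duration=trace.duration)
    return trace, ttrace, train


# ---------------------------------------------------------------------------
# scenario suite
#
# Conditions chosen to reproduce the phenomenology of sound-driven
# intracellular recordings: a fast fluctuating current (mean 40 pA, SD
# 120 pA, 3 ms correlation time) riding on a slow envelope (the stimulus-
# evoked depolarization, tens of ms), ground-truth steady-state curves
# that stay above the diagonal theta = V (so spikes require depolarizing
# faster than the threshold adapts, and measured onset voltages span
# several mV, overlapping the sub-threshold voltage distribution), and
# sharp (kink-like) spike initiation as observed at the soma in vivo.

#: Ground-truth threshold parameters per validation scenario.
SCENARIOS: dict[str, ThresholdModelParams] = {
    "constant": ThresholdModelParams(
        tau_theta=3.0, V_i=-59.0, theta_offset=-55.0, alpha=0.0, beta=0.0, k_a=7.0),
    "rectified": ThresholdModelParams(
        tau_theta=3.0, V_i=-59.0, theta_offset=-57.0, alpha=0.0, beta=1.0, k_a=3.0),
    "linear": ThresholdModelParams(
        tau_theta=5.0, V_i=-59.0, theta_offset=-51.0, alpha=1.0, beta=1.0, k_a=3.0),
    "fast_rectified": ThresholdModelParams(
        tau_theta=0.3, V_i=-59.0, theta_offset=-59.0, alpha=0.0, beta=1.0, k_a=3.0),
}

#: Fast-current settings per scenario (current_grid handled separately).
_SCENARIO_OU = {
    "constant": dict(mean=40.0, sd=120.0, tau_I=3.0),
    "rectified": dict(mean=40.0, sd=120.0, tau_I=3.0),
    "linear": dict(mean=40.0, sd=120.0, tau_I=3.0),
    "fast_rectified": dict(mean=40.0, sd=120.0, tau_I=0.5),
}

#: Slow stimulus-envelope component common to all scenarios (pA, ms).
ENVELOPE_SD = 150.0
ENVELOPE_TAU = 50.0

#: Sharp-initiation neuron used for the validation scenarios: somatic
#: onsets in vivo are kink-like, and the coincidence window (84 us) can
#: only constrain threshold dynamics when crossings happen at the speed
#: of the sub-threshold drive rather than inside an explosive upstroke.
SCENARIO_EIF = EIFParams(Delta_T=0.0)

CURRENT_GRID_MEANS = (20.0, 110.0, 200.0)   # pA
CURRENT_GRID_SDS = (50.0, 225.0, 400.0)     # pA
MIN_SPIKES = 20
MAX_RATE_HZ = 200.0


def _scenario_current(ou: OUParams, env_seed: int) -> np.ndarray:
    """Fast OU drive plus the slow stimulus-envelope component."""
    I = ou_current(ou)
    env = ou_current(OUParams(mean=0.0, sd=ENVELOPE_SD, tau_I=ENVELOPE_TAU,
                              duration=ou.duration, dt=ou.dt, seed=env_seed))
    return I + env


def make_fixture_suite(
    scenario: str,
    seed: int,
    duration_ms: float = 20000.0,
    eif: EIFParams = SCENARIO_EIF,
    n_traces: int = 1,
) -> dict:
    """Generate a named validation scenario.

    Returns a manifest dict with the ground-truth parameters and, per
    trace, the voltage trace, the hidden threshold trace, the true spike
    train and the OU settings used.  For ``current_grid``, one trace per
    surviving (mean, SD) grid cell after screening for at least
    ``MIN_SPIKES`` spikes and a firing rate below ``MAX_RATE_HZ``.
    """
    rng = np.random.default_rng(seed)
    entries = []
    if scenario == "current_grid":
        thr = SCENARIOS["rectified"]
        cells = [(m, s) for m in CURRENT_GRID_MEANS for s in CURRENT_GRID_SDS]
        for m, s in cells:
            sub = int(rng.integers(0, 2**30 - 1))
            ou = OUParams(mean=m, sd=s, tau_I=3.0, duration=duration_ms, seed=sub)
            trace, theta, train = simulate_eif_adaptive(
                eif, thr, _scenario_current(ou, sub + 2**30),
                meta={"condition": f"mean{m:g}_sd{s:g}", "protocol": "grid"})
            if len(train) < MIN_SPIKES or train.rate_hz >= MAX_RATE_HZ:
                continue
            entries.append(dict(trace=trace, theta=theta, spikes=train, ou=ou))
    else:
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}; "
                             f"choose from {sorted(SCENARIOS)} or 'current_grid'")
        thr = SCENARIOS[scenario]
        for k in range(n_traces):
            sub = int(rng.integers(0, 2**30 - 1))
            ou = OUParams(duration=duration_ms, seed=sub, **_SCENARIO_OU[scenario])
            trace, theta, train = simulate_eif_adaptive(
                eif, thr, _scenario_current(ou, sub + 2**30),
                meta={"condition": f"{scenario}_{k}", "protocol": scenario})
            entries.append(dict(trace=trace, theta=theta, spikes=train, ou=ou))
    return {
        "scenario": scenario,
        "seed": seed,
        "ground_truth": thr,
        "eif": eif,
        "entries": entries,
    }


def excise_spikes_to_reset(
    trace: VoltageTrace,
    spikes: SpikeTrain,
    eif: EIFParams,
) -> VoltageTrace:
    """Replace each stylized spike waveform with the reset-held voltage.

    From one sample after each registered spike through the end of the
    refractory period the voltage is set to ``V_reset`` — exactly the
    input the generative threshold integrated during that span.  Used to
    prepare simulated traces for fitting, so the fitted model sees the
    same drive as the hidden ground-truth threshold.
    """
    V = trace.samples.copy()
    w = max(1, int(round(eif.refractory / trace.dt)))
    n = V.size
    for t in spikes.times:
        i = int(round((t - trace.t0) / trace.dt))
        V[i + 1:min(n, i + w)] = eif.V_reset
    return VoltageTrace(samples=V, dt=trace.dt, t0=trace.t0,
                        meta=dict(trace.meta))


def manifest_summary(suite: dict) -> str:
    """Deterministic JSON summary of a fixture suite (for manifests)."""
    return json.dumps({
        "scenario": suite["scenario"],
        "seed": suite["seed"],
        "ground_truth": suite["ground_truth"].to_dict(),
        "eif": asdict(suite["eif"]),
        "entries": [
            {"n_samples": len(e["trace"]), "n_spikes": len(e["spikes"]),
             "ou": asdict(e["ou"]), "meta": e["trace"].meta}
            for e in suite["entries"]
        ],
    }, indent=2, sort_keys=True)


def make_psp_trace(
    amplitude_mV: float,
    tau_decay_ms: float,
    baseline_mV: float = -70.0,
    duration_ms: float = 100.0,
    onset_ms: float = 20.0,
    dt: float = DEFAULT_DT_MS,
) -> VoltageTrace:
    """A single alpha-function postsynaptic potential on a constant baseline.

    V(t) = baseline + A·(s/τ)·exp(1 − s/τ) for s = t − onset ≥ 0, which
    peaks at exactly ``amplitude_mV`` above baseline at s = τ.
    """
    if amplitude_mV < 0:
        raise ParameterError("amplitude must be >= 0")
    t = np.arange(int(round(duration_ms / dt))) * dt
    s = t - onset_ms
    psp = np.where(s >= 0,
                   amplitude_mV * (np.maximum(s, 0) / tau_decay_ms)
                   * np.exp(1.0 - np.maximum(s, 0) / tau_decay_ms),
                   0.0)
    return VoltageTrace(samples=baseline_mV + psp, dt=dt,
                        meta={"kind": "psp", "amplitude_mV": amplitude_mV,
                              "tau_ms": tau_decay_ms})
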