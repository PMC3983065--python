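"""Ground-truth validation protocols.

Each function runs one of the package's standard validation experiments on
synthetic data with a known threshold and returns plain numbers: parameter
recovery per scenario, the fixed-τ profile, stimulus-independence of the
fitted curve across a current grid, chance-level behaviour of the gamma
score, the integration-oracle error, and the effective-signal properties.
These are the experiments behind the package's claims; the acceptance
script and the acceptance tests both call them.
"""

from __future__ import annotations

import numpy as np

from .coincidence import curve_distance, gamma_factor
from .effective import es_summary, effective_signal
from .fitting import (FitConfig, FittedTrace, fit_threshold_model,
                      recovery_traces, sweep_fixed_tau)
from .model import (SpikeTrain, ThresholdModelParams, VoltageTrace,
                    integrate_threshold, steady_state_threshold)
from .synth import OUParams, make_fixture_suite, ou_current, SCENARIOS

__all__ = [
    "recovery_config",
    "assess_recovery",
    "tau_sweep_profile",
    "current_grid_consistency",
    "gamma_chance_level",
    "integration_oracle_error",
    "effective_signal_properties",
    "highpass_gain_error",
]


def recovery_config(seed: int, **overrides) -> FitConfig:
    """Optimizer settings used for all ground-truth recovery fits."""
    kw = dict(seed=seed, population=24, max_evals=6000, restarts=3,
              gamma_target=0.95)
    kw.update(overrides)
    return FitConfig(**kw)


def _curve_recovery(fitted: ThresholdModelParams,
                    truth: ThresholdModelParams,
                    fts: list[FittedTrace]) -> dict:
    """Bias and bias-removed mean absolute curve error over the voltage
    range the spikes actually probe (measured onset envelope ± 2 mV)."""
    onsets = np.array([s.onset_voltage for ft in fts for s in (ft.measured or [])])
    V = np.linspace(onsets.min() - 2.0, onsets.max() + 2.0, 400)
    diff = (np.asarray(steady_state_threshold(fitted, V))
            - np.asarray(steady_state_threshold(truth, V)))
    bias = float(diff.mean())
    return {"bias_mV": bias, "curve_mad_mV": float(np.abs(diff - bias).mean())}


def assess_recovery(scenario: str, seed: int,
                    duration_ms: float = 20000.0, **config_overrides) -> dict:
    """Fit one seeded dataset of a scenario and compare with its truth."""
    suite = make_fixture_suite(scenario, seed=seed, duration_ms=duration_ms)
    truth = suite["ground_truth"]
    fts = recovery_traces(suite)
    cfg = recovery_config(seed + 1000, **config_overrides)
    res = fit_threshold_model(fts, cfg, subset_id=f"{scenario}:{seed}")
    out = {
        "scenario": scenario,
        "seed": seed,
        "gamma": res.gamma_train,
        "tau_fit_ms": res.params.tau_theta,
        "tau_true_ms": truth.tau_theta,
        "tau_ratio": res.params.tau_theta / truth.tau_theta,
        "V_i_fit_mV": res.params.V_i,
        "V_i_err_mV": res.params.V_i - truth.V_i,
        "params": res.params,
    }
    out.update(_curve_recovery(res.params, truth, fts))
    return out


def tau_sweep_profile(seed: int, tau_grid=(0.1, 0.3, 1.0, 3.0, 10.0),
                      duration_ms: float = 20000.0,
                      **config_overrides) -> list[dict]:
    """Γ profile over fixed time constants on the rectified scenario.

    The profile should peak at the generative τ (3 ms) and fall off on
    both sides: moving the time constant away from its optimum degrades
    the fit even when all other parameters are re-optimized.
    """
    suite = make_fixture_suite("rectified", seed=seed, duration_ms=duration_ms)
    fts = recovery_traces(suite)
    cfg = recovery_config(seed + 1000, max_evals=4000, **config_overrides)
    rows = sweep_fixed_tau(fts, tau_grid, cfg)
    return [{"tau_ms": r["tau_ms"], "gamma": r["gamma"], "ev": r["ev"]}
            for r in rows]


def current_grid_consistency(seed: int, duration_ms: float = 20000.0,
                             **config_overrides) -> dict:
    """Stimulus independence: separate fits across the input-current grid.

    Fits the model independently on each surviving grid cell and compares
    the fitted steady-state curves with each other and with the diagonal
    θ = V over the pooled sub-threshold voltage range.  Consistent fits
    give pairwise distances far below the distance to the diagonal.
    """
    suite = make_fixture_suite("current_grid", seed=seed,
                               duration_ms=duration_ms)
    fts_all = recovery_traces(suite)
    fitted = []
    for k, ft in enumerate(fts_all):
        cfg = recovery_config(seed + 1000 + 17 * k, **config_overrides)
        res = fit_threshold_model([ft], cfg,
                                  subset_id=ft.trace.meta.get("condition", str(k)))
        fitted.append(res.params)
    pooled = np.concatenate([e["trace"].samples for e in suite["entries"]])
    sub = pooled[pooled < -35.0]
    v_lo, v_hi = float(np.percentile(sub, 1)), float(np.percentile(sub, 99))
    d = curve_distance(fitted, v_lo, v_hi)
    return {
        "n_cells": len(fitted),
        "mean_pairwise_mV": d["mean_pairwise"],
        "mean_to_diagonal_mV": d["mean_to_diagonal"],
        "ratio": d["mean_to_diagonal"] / d["mean_pairwise"],
    }


def gamma_chance_level(seed: int, n_real: int = 200, rate_hz: float = 20.0,
                       duration_s: float = 100.0, delta_ms: float = 0.084) -> dict:
    """Mean Γ of rate-matched independent Poisson predictions (≈ 0)."""
    rng = np.random.default_rng(seed)
    duration = duration_s * 1000.0
    scale = 1000.0 / rate_hz
    n_draw = int(2 * rate_hz * duration_s)
    gammas = []
    for _ in range(n_real):
        rec = np.cumsum(rng.exponential(scale, n_draw))
        rec = rec[rec < duration]
        pred = np.cumsum(rng.exponential(scale, n_draw))
        pred = pred[pred < duration]
        g = gamma_factor(SpikeTrain(rec, duration), SpikeTrain(pred, duration),
                         delta_ms, duration)
        gammas.append(g.gamma)
    return {"mean_gamma": float(np.mean(gammas)), "n": n_real}


def integration_oracle_error(seed: int, duration_ms: float = 1000.0,
                             refine: int = 20) -> float:
    """Max |exact-update − fine-Euler| threshold error on an OU-driven trace (mV)."""
    dt = 1000.0 / 42000.0
    v = -65.0 + 6.0 * ou_current(OUParams(mean=0.0, sd=1.0, tau_I=3.0,
                                          duration=duration_ms, dt=dt,
                                          seed=seed))
    trace = VoltageTrace(v, dt=dt)
    params = SCENARIOS["rectified"]
    theta = integrate_threshold(params, trace)
    s = np.asarray(steady_state_threshold(params, trace.samples))
    dt_f = dt / refine
    th = s[0]
    fine = np.empty(len(trace))
    for i in range(len(trace)):
        fine[i] = th
        for _ in range(refine):
            th += dt_f / params.tau_theta * (s[i] - th)
    return float(np.max(np.abs(theta.samples - fine)))


def effective_signal_properties(seed: int, n_seeds: int = 10,
                                duration_ms: float = 10000.0) -> dict:
    """σ and HHW reduction by fast threshold adaptation, across seeds.

    Simulates the fast rectified threshold (τ_θ = 0.3 ms) under a
    slow+fast mixed current strong enough to hold the voltage mostly
    above the knee — the regime the effect lives in: above the knee the
    steady-state curve has slope 1, so the threshold tracks the voltage
    with a 0.3 ms lag and the effective signal is the high-pass residual.
    Its standard deviation and autocorrelation width must come out below
    the voltage's in every run.
    """
    from .synth import SCENARIO_EIF, simulate_eif_adaptive, ENVELOPE_TAU
    # fast threshold with a few-mV margin above the knee: the neuron sits
    # above the knee without firing tonically, so the threshold tracks
    # the voltage one-for-one and the ES is the high-pass residual
    thr = ThresholdModelParams(tau_theta=0.3, V_i=-59.0, theta_offset=-56.0,
                               alpha=0.0, beta=1.0, k_a=3.0)
    wins_sigma = wins_hhw = 0
    ratios_sigma, ratios_hhw = [], []
    for k in range(n_seeds):
        # mean raised and envelope slightly softened relative to the
        # recovery scenarios so the voltage stays above the knee ~90% of
        # the time
        I = (ou_current(OUParams(mean=250.0, sd=120.0, tau_I=0.5,
                                 duration=duration_ms, seed=seed + k))
             + ou_current(OUParams(mean=0.0, sd=100.0,
                                   tau_I=ENVELOPE_TAU, duration=duration_ms,
                                   seed=seed + k + 40000)))
        trace, _, spikes = simulate_eif_adaptive(SCENARIO_EIF, thr, I)
        ft = FittedTrace.from_trace(trace)
        # the slow envelope dominates the voltage autocorrelation, so the
        # lag window must extend well past its 50 ms correlation time
        summ = es_summary(trace, thr,
                          spike_onsets_ms=ft.rec_times, max_lag_ms=400.0)
        wins_sigma += summ.sigma_ES < summ.sigma_V
        wins_hhw += summ.hhw_ES < summ.hhw_V
        ratios_sigma.append(summ.sigma_ES / summ.sigma_V)
        ratios_hhw.append(summ.hhw_ES / summ.hhw_V)
    return {
        "n_seeds": n_seeds,
        "sigma_reduced_count": int(wins_sigma),
        "hhw_reduced_count": int(wins_hhw),
        "mean_sigma_ratio": float(np.mean(ratios_sigma)),
        "mean_hhw_ratio": float(np.mean(ratios_hhw)),
    }


def highpass_gain_error(tau_theta: float = 3.0) -> float:
    """Worst relative error of the ES sinusoid gain vs ωτ/√(1+ω²τ²).

    Spans two decades of angular frequency in the linear regime above the
    knee (β = 1, small amplitude).
    """
    dt = 1000.0 / 42000.0
    p = ThresholdModelParams(tau_theta=tau_theta, V_i=-80.0,
                             theta_offset=-60.0, alpha=0.0, beta=1.0, k_a=0.5)
    worst = 0.0
    for period in (2.0, 6.3, 20.0, 63.0, 200.0):
        omega = 2 * np.pi / period
        n_per = max(6, int(600 / period))
        t = np.arange(int(n_per * period / dt)) * dt
        v = -55.0 + 0.5 * np.sin(omega * t)
        trace = VoltageTrace(v, dt=dt)
        theta = integrate_threshold(p, trace)
        es = effective_signal(trace, theta)
        tail = es[len(es) // 2:]
        gain = (tail.max() - tail.min()) / 1.0
        expected = omega * tau_theta / np.sqrt(1 + (omega * tau_theta) ** 2)
        worst = max(worst, abs(gain - expected) / expected)
    return float(worst)
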