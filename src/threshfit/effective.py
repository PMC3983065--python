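"""Functional consequences of threshold adaptation: the effective signal.

Because the threshold tracks slow voltage fluctuations, the quantity the
spike generator actually compares to a fixed criterion is the *effective
signal* ES(t) = V(t) − θ(t): a spike is produced when the ES crosses
0 mV.  Voltage dynamics with an adaptive threshold are therefore
equivalent to ES dynamics with a fixed threshold.  Threshold adaptation
acts as a high-pass filter on the voltage, so the ES has a smaller
standard deviation and a much shorter correlation time than the raw
voltage — the neuron's integration window, read from the half-height
width (HHW) of the autocorrelation, shrinks toward the threshold time
constant.  For white-noise input, HHW/(2·ln 2) estimates the membrane
time constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .model import (ThresholdModelParams, ThresholdTrace, VoltageTrace,
                    integrate_threshold)

__all__ = [
    "EffectiveSignalSummary",
    "effective_signal",
    "autocorrelogram",
    "hhw",
    "es_summary",
]

TWO_LN2 = 2.0 * np.log(2.0)


@dataclass(frozen=True)
class EffectiveSignalSummary:
    sigma_V: float     # mV
    sigma_ES: float    # mV
    hhw_V: float       # ms
    hhw_ES: float      # ms

    @property
    def tau_m_est(self) -> float:
        """Membrane time constant implied by hhw_V under white-noise input (ms)."""
        return self.hhw_V / TWO_LN2

    def to_dict(self) -> dict:
        return {"sigma_V_mV": self.sigma_V, "sigma_ES_mV": self.sigma_ES,
                "hhw_V_ms": self.hhw_V, "hhw_ES_ms": self.hhw_ES,
                "tau_m_est_ms": self.tau_m_est}


def effective_signal(trace: VoltageTrace, theta: ThresholdTrace) -> np.ndarray:
    """ES(t) = V(t) − θ(t); upward zero crossings are the raw spike criterion."""
    if len(trace) != len(theta):
        raise ValueError("voltage and threshold traces are misaligned")
    return trace.samples - theta.samples


def _excision_mask(n: int, dt: float, onsets_ms, excision_ms: float) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    w = max(1, int(round(excision_ms / dt)))
    for t in np.asarray(onsets_ms, dtype=float):
        i = int(round(t / dt))
        mask[max(0, i):min(n, i + w)] = False
    return mask


def autocorrelogram(
    signal: np.ndarray,
    dt: float,
    spike_onsets_ms=(),
    excision_ms: float = 1.0,
    max_lag_ms: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-subtracted autocorrelation with spike windows excised.

    Windows [onset, onset + excision) around each spike are removed;
    lagged products are accumulated only over index pairs that are both
    outside excisions, with biased normalization so the zero-lag value
    is 1.  Returns (lags_ms, acf).
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n * dt < 10.0 * max_lag_ms:
        raise ValueError("trace must be at least 10x longer than max_lag")
    mask = _excision_mask(n, dt, spike_onsets_ms, excision_ms)
    if mask.sum() < 0.5 * n:
        raise ValueError("more than half of the samples are excised")
    xm = np.where(mask, x - x[mask].mean(), 0.0)
    nlag = int(round(max_lag_ms / dt))
    # products where either sample is excised contribute exactly zero
    corr = fftconvolve(xm, xm[::-1])[n - 1:n + nlag]
    if corr[0] <= 0:
        raise ValueError("signal has zero variance on the retained samples")
    acf = corr / corr[0]
    lags = np.arange(nlag + 1) * dt
    return lags, acf


def hhw(lags: np.ndarray, acf: np.ndarray) -> float:
    """Full width of the autocorrelation at half its zero-lag height (ms).

    The acf must be normalized to 1 at lag 0; the first downward crossing
    of 0.5 is located by linear interpolation, and the (symmetric) full
    width is twice that lag.
    """
    if not np.isclose(acf[0], 1.0):
        raise ValueError("acf must be normalized to 1 at lag 0")
    below = np.flatnonzero(acf < 0.5)
    if below.size == 0:
        raise ValueError("acf never drops below 0.5 within max_lag; "
                         "recompute with a longer max_lag")
    i = below[0]
    # linear interpolation between the bracketing lags
    frac = (acf[i - 1] - 0.5) / (acf[i - 1] - acf[i])
    half_lag = lags[i - 1] + frac * (lags[i] - lags[i - 1])
    return float(2.0 * half_lag)


def es_summary(
    trace: VoltageTrace,
    params: ThresholdModelParams,
    spike_onsets_ms=(),
    excision_ms: float = 1.0,
    max_lag_ms: float = 20.0,
) -> EffectiveSignalSummary:
    """σ and autocorrelation HHW of the voltage vs the effective signal.

    Both statistics are computed on spike-excised data, with the threshold
    obtained by integrating the fitted model along the trace.
    """
    theta = integrate_threshold(params, trace)
    es = effective_signal(trace, theta)
    mask = _excision_mask(len(trace), trace.dt, spike_onsets_ms, excision_ms)
    sigma_V = float(trace.samples[mask].std())
    sigma_ES = float(es[mask].std())
    lags, acf_V = autocorrelogram(trace.samples, trace.dt, spike_onsets_ms,
                                  excision_ms, max_lag_ms)
    _, acf_ES = autocorrelogram(es, trace.dt, spike_onsets_ms,
                                excision_ms, max_lag_ms)
    return EffectiveSignalSummary(sigma_V=sigma_V, sigma_ES=sigma_ES,
                                  hhw_V=hhw(lags, acf_V),
                                  hhw_ES=hhw(lags, acf_ES))
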