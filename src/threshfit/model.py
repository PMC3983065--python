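"""Adaptive spike-threshold dynamics.

The spike threshold :math:`\\theta(t)` relaxes toward a voltage-dependent
steady state :math:`\\theta_\\infty(V)` with a single time constant
:math:`\\tau_\\theta`:

.. math::

    \\tau_\\theta \\frac{d\\theta}{dt} = \\theta_\\infty(V(t)) - \\theta

The steady-state curve is near-constant below a critical ("knee") voltage
``V_i`` and rises approximately linearly above it, as predicted by sodium
channel inactivation.  It is parameterized as a softplus interpolation
between two asymptotic slopes:

.. math::

    \\theta_\\infty(V) = \\theta_0 + \\alpha (V - V_i)
        + (\\beta - \\alpha)\\, k_a \\ln(1 + e^{(V - V_i)/k_a})

with slope ``alpha`` far below the knee, ``beta`` far above it, and the
sharpness of the bend set by ``k_a``.  A spike is predicted the moment the
membrane potential reaches the threshold; each predicted spike is followed
by a short refractory period during which no further spike is emitted (the
threshold itself keeps evolving and is never reset).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "ThresholdModelParams",
    "VoltageTrace",
    "ThresholdTrace",
    "SpikeTrain",
    "steady_state_threshold",
    "integrate_threshold",
    "predict_spikes",
    "blank_spike_waveforms",
    "DEFAULT_REFRACTORY_MS",
]

#: Refractory period after a predicted spike (ms).
DEFAULT_REFRACTORY_MS = 0.5


class ParameterError(ValueError):
    """Raised when model parameters or trace inputs fail validation."""


@dataclass(frozen=True)
class ThresholdModelParams:
    """The six scalars defining the adaptive threshold model.

    Parameters
    ----------
    tau_theta : float
        Time constant of threshold adaptation (ms, > 0).
    V_i : float
        Critical ("knee") voltage of the steady-state curve (mV).
    theta_offset : float
        Steady-state threshold at the knee asymptote (mV): the value the
        lower linear branch extrapolates to at ``V = V_i``.
    alpha : float
        Dimensionless slope of the steady-state curve far below ``V_i``.
    beta : float
        Dimensionless slope far above ``V_i``; ``beta >= alpha``.
    k_a : float
        Curvature scale of the bend (mV, > 0).
    """

    tau_theta: float
    V_i: float
    theta_offset: float
    alpha: float
    beta: float
    k_a: float

    def __post_init__(self) -> None:
        vals = (self.tau_theta, self.V_i, self.theta_offset,
                self.alpha, self.beta, self.k_a)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError(f"non-finite parameter in {vals}")
        if self.tau_theta <= 0:
            raise ParameterError(f"tau_theta must be > 0, got {self.tau_theta}")
        if self.k_a <= 0:
            raise ParameterError(f"k_a must be > 0, got {self.k_a}")
        if self.beta < self.alpha:
            raise ParameterError(
                f"beta ({self.beta}) must be >= alpha ({self.alpha}); "
                "the steady-state curve bends upward")

    # -- serialization ---------------------------------------------------
    _JSON_KEYS = {
        "tau_theta": "tau_theta_ms",
        "V_i": "V_i_mV",
        "theta_offset": "theta_offset_mV",
        "alpha": "alpha",
        "beta": "beta",
        "k_a": "k_a_mV",
    }

    def to_dict(self) -> dict:
        return {jk: getattr(self, f) for f, jk in self._JSON_KEYS.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdModelParams":
        kwargs = {f: float(d[jk]) for f, jk in cls._JSON_KEYS.items()}
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ThresholdModelParams":
        return cls.from_dict(json.loads(s))

    def as_array(self) -> np.ndarray:
        """Parameter vector in canonical order (tau, V_i, offset, alpha, beta, k_a)."""
        return np.array([self.tau_theta, self.V_i, self.theta_offset,
                         self.alpha, self.beta, self.k_a])

    @classmethod
    def from_array(cls, x) -> "ThresholdModelParams":
        t, vi, off, a, b, ka = (float(v) for v in x)
        return cls(tau_theta=t, V_i=vi, theta_offset=off, alpha=a, beta=b, k_a=ka)

    def replace(self, **kw) -> "ThresholdModelParams":
        return replace(self, **kw)


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane potential.

    Attributes
    ----------
    samples : ndarray
        Voltage values (mV), finite, non-empty.
    dt : float
        Sampling interval (ms, > 0).
    t0 : float
        Time of the first sample (ms).
    meta : dict
        Free-form metadata (cell id, condition label, protocol tag).
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ParameterError("samples must be a non-empty 1-D array")
        if not (self.dt > 0) or not math.isfinite(self.dt):
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        if not np.all(np.isfinite(self.samples)):
            bad = np.flatnonzero(~np.isfinite(self.samples))
            raise ParameterError(
                f"non-finite samples at indices {bad[:10].tolist()}"
                + ("..." if bad.size > 10 else ""))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration (ms)."""
        return self.samples.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.samples.size)


@dataclass
class ThresholdTrace:
    """Threshold values aligned sample-for-sample with a source VoltageTrace."""

    samples: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.samples.size)


@dataclass
class SpikeTrain:
    """Ordered spike (onset) times in ms, with the duration of the trace."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ParameterError("spike times must be strictly increasing")
        if self.times.size and (self.times[0] < 0 or self.times[-1] >= self.duration + 1e-9):
            raise ParameterError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return self.times.size

    @property
    def rate_hz(self) -> float:
        """Mean firing rate (Hz); duration is in ms."""
        return 1000.0 * self.times.size / self.duration


# ---------------------------------------------------------------------------

def _softplus(x: np.ndarray) -> np.ndarray:
    # ln(1 + e^x), computed as x + ln(1 + e^-x) for x > 0 to avoid overflow
    return np.logaddexp(0.0, x)


def steady_state_threshold(
    params: ThresholdModelParams,
    V: Union[float, np.ndarray],
) -> Union[float, np.ndarray]:
    """Steady-state threshold curve θ∞(V), elementwise.

    Slope tends to ``alpha`` for V far below the knee ``V_i`` and to
    ``beta`` far above it; the transition has curvature scale ``k_a``.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ParameterError("voltage input must be finite")
    x = (V - params.V_i) / params.k_a
    out = (params.theta_offset
           + params.alpha * (V - params.V_i)
           + (params.beta - params.alpha) * params.k_a * _softplus(x))
    return out if out.ndim else float(out)


def integrate_threshold(
    params: ThresholdModelParams,
    trace: VoltageTrace,
    theta0: Optional[float] = None,
) -> ThresholdTrace:
    """Integrate the threshold ODE along a voltage trace.

    Uses the exact exponential update with the voltage held constant over
    each sampling interval:

        θ[n+1] = θ∞(V[n]) + (θ[n] − θ∞(V[n])) · exp(−dt/τ)

    which is unconditionally stable even when ``tau_theta`` is much smaller
    than the sampling interval.  ``theta0`` defaults to θ∞ of the first
    sample, which removes the arbitrary initial transient.
    """
    if params.tau_theta < trace.dt / 100.0:
        warnings.warn(
            f"tau_theta ({params.tau_theta} ms) is far below the sampling "
            f"interval ({trace.dt} ms); threshold follows the steady-state "
            "curve essentially instantaneously", stacklevel=2)
    s = steady_state_threshold(params, trace.samples)
    if theta0 is None:
        theta0 = float(s[0])
    a = math.exp(-trace.dt / params.tau_theta)
    # First-order IIR: theta[n] = a*theta[n-1] + (1-a)*s[n-1], theta[0]=theta0
    theta = lfilter([0.0, 1.0 - a], [1.0, -a], s, zi=np.array([theta0]))[0]
    return ThresholdTrace(samples=theta, dt=trace.dt, t0=trace.t0)


def predict_spikes(
    params: ThresholdModelParams,
    trace: VoltageTrace,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
    theta0: Optional[float] = None,
) -> tuple[SpikeTrain, ThresholdTrace]:
    """Predict spike times from a voltage trace under the threshold model.

    A spike is emitted at the first sample where ``V >= θ`` outside the
    refractory window of the previous predicted spike.  The threshold keeps
    integrating through spikes and refractory periods (no reset).

    Returns the predicted spike train (times relative to trace start) and
    the full threshold trace.
    """
    theta = integrate_threshold(params, trace, theta0=theta0)
    candidates = np.flatnonzero(trace.samples >= theta.samples)
    spike_idx = []
    last = -math.inf
    for i in candidates:
        if (i - last) * trace.dt >= refractory_ms - 1e-12:
            spike_idx.append(i)
            last = i
    times = np.asarray(spike_idx, dtype=float) * trace.dt
    return SpikeTrain(times=times, duration=trace.duration), theta


def blank_spike_waveforms(
    trace: VoltageTrace,
    onset_times_ms: np.ndarray,
    blank_ms: float = 1.0,
) -> VoltageTrace:
    """Excise spike waveforms before driving the threshold ODE.

    Replaces ``[onset, onset + blank_ms)`` with the voltage at onset, so the
    steady-state drive during the spike is held at the onset voltage.  Off
    the default path: the raw trace, spikes included, is normally passed
    through the model unmodified.
    """
    V = trace.samples.copy()
    n = V.size
    for t in np.asarray(onset_times_ms, dtype=float):
        i0 = int(round((t - trace.t0) / trace.dt))
        if not 0 <= i0 < n:
            continue
        i1 = min(n, i0 + max(1, int(round(blank_ms / trace.dt))))
        V[i0:i1] = V[i0]
    return VoltageTrace(samples=V, dt=trace.dt, t0=trace.t0, meta=dict(trace.meta))
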