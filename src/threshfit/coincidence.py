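"""Spike-train comparison scores used to train and evaluate the model.

The central quantity is the gamma coincidence factor Γ: the number of
predicted spikes falling within a coincidence window δ of a recorded
spike, corrected for the coincidences a rate-matched Poisson process would
produce by chance, and normalized so that Γ = 1 for a perfect prediction
and Γ ≈ 0 for chance-level prediction:

    Γ = 1/(1 − 2νδ) · (N_coinc − 2νδ·N_pred) / ((N_rec + N_pred)/2)

with ν the recorded firing rate.  Also here: the false-alarm rate, the
explained variance of the measured onset voltage, and the mean distance
between steady-state threshold curves (and between a curve and the
diagonal θ = V) used to compare fits across recording conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SpikeTrain, ThresholdModelParams, steady_state_threshold

__all__ = [
    "GammaScore",
    "count_coincidences",
    "match_coincidences",
    "gamma_factor",
    "false_alarm_rate",
    "explained_variance",
    "curve_distance",
    "DEFAULT_DELTA_MS",
]

#: Coincidence half-window δ (ms); 84 µs, about two samples at 24 kHz.
DEFAULT_DELTA_MS = 0.084


@dataclass(frozen=True)
class GammaScore:
    gamma: float
    n_coinc: int
    n_rec: int
    n_pred: int
    rate_rec: float       # Hz
    delta: float          # ms

    def to_dict(self) -> dict:
        return {"gamma": self.gamma, "n_coinc": self.n_coinc,
                "n_rec": self.n_rec, "n_pred": self.n_pred,
                "rate_rec_hz": self.rate_rec, "delta_ms": self.delta}


def match_coincidences(
    rec: SpikeTrain | np.ndarray,
    pred: SpikeTrain | np.ndarray,
    delta_ms: float = DEFAULT_DELTA_MS,
) -> list[tuple[int, int]]:
    """One-to-one pairing of recorded and predicted spikes within δ.

    Greedy earliest-first sweep over both (sorted) trains; each spike
    matches at most once.  For interval-overlap graphs of this form the
    greedy sweep attains the maximum-cardinality matching.
    """
    tr = rec.times if isinstance(rec, SpikeTrain) else np.asarray(rec, float)
    tp = pred.times if isinstance(pred, SpikeTrain) else np.asarray(pred, float)
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < tr.size and j < tp.size:
        d = tr[i] - tp[j]
        if abs(d) <= delta_ms:
            pairs.append((i, j))
            i += 1
            j += 1
        elif d > 0:
            j += 1
        else:
            i += 1
    return pairs


def count_coincidences(
    rec: SpikeTrain | np.ndarray,
    pred: SpikeTrain | np.ndarray,
    delta_ms: float = DEFAULT_DELTA_MS,
) -> int:
    """Number of one-to-one coincidences within ±δ (|Δt| ≤ δ)."""
    return len(match_coincidences(rec, pred, delta_ms))


def gamma_factor(
    rec: SpikeTrain,
    pred: SpikeTrain,
    delta_ms: float = DEFAULT_DELTA_MS,
    duration_ms: float | None = None,
) -> GammaScore:
    """Gamma coincidence factor between recorded and predicted trains.

    Γ = 1 means the prediction is perfect at temporal resolution δ; Γ = 0
    means no more coincidences than a Poisson process at the recorded rate
    would produce by chance.
    """
    if duration_ms is None:
        duration_ms = rec.duration
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    n_rec = len(rec)
    n_pred = len(pred)
    if n_rec == 0:
        raise ValueError("recorded train is empty; gamma undefined")
    nu = n_rec / duration_ms          # spikes per ms
    chance = 2.0 * nu * delta_ms
    if chance >= 1.0:
        raise ValueError(
            f"2*nu*delta = {chance:.3f} >= 1: normalization undefined "
            "(rate too high for this coincidence window)")
    n_coinc = count_coincidences(rec, pred, delta_ms)
    gamma = ((n_coinc - chance * n_pred) / ((n_rec + n_pred) / 2.0)
             / (1.0 - chance))
    return GammaScore(gamma=float(gamma), n_coinc=n_coinc, n_rec=n_rec,
                      n_pred=n_pred, rate_rec=1000.0 * nu, delta=delta_ms)


def false_alarm_rate(
    rec: SpikeTrain,
    pred: SpikeTrain,
    delta_ms: float = DEFAULT_DELTA_MS,
) -> float:
    """Predicted spikes with no coincident recorded spike, as % of recorded.

    Can exceed 100% for a grossly over-firing prediction.
    """
    if len(rec) == 0:
        raise ValueError("recorded train is empty; false-alarm rate undefined")
    n_coinc = count_coincidences(rec, pred, delta_ms)
    return 100.0 * (len(pred) - n_coinc) / len(rec)


def explained_variance(
    measured_onset_V: np.ndarray,
    predicted_theta: np.ndarray,
) -> float:
    """Fraction of measured spike-onset-voltage variance explained.

    EV = 1 − Σ(θ̂ᵢ − θᵢ)² / Σ(θᵢ − mean θ)², over coincidence-matched
    spikes.  EV ≤ 1; negative when the prediction is worse than the mean.
    """
    theta = np.asarray(measured_onset_V, dtype=float)
    theta_hat = np.asarray(predicted_theta, dtype=float)
    if theta.size != theta_hat.size:
        raise ValueError("paired lists must have equal length")
    if theta.size < 3:
        raise ValueError("need at least 3 matched spikes")
    ss_tot = float(np.sum((theta - theta.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("measured onset voltages have zero variance")
    ss_res = float(np.sum((theta_hat - theta) ** 2))
    return 1.0 - ss_res / ss_tot


def curve_distance(
    params_list: list[ThresholdModelParams],
    V_min: float,
    V_max: float,
    n_grid: int = 1000,
) -> dict:
    """Mean distances between steady-state threshold curves.

    ``mean_pairwise`` averages, over all unordered pairs of parameter sets,
    the voltage-averaged absolute difference between their θ∞ curves on
    [V_min, V_max] (trapezoidal rule).  ``mean_to_diagonal`` replaces the
    second curve by the identity line θ = V, averaged over all sets.
    """
    if V_max <= V_min:
        raise ValueError("degenerate voltage range")
    V = np.linspace(V_min, V_max, n_grid)
    curves = [np.asarray(steady_state_threshold(p, V)) for p in params_list]
    span = V_max - V_min

    def mean_abs(diff):
        return float(np.trapezoid(np.abs(diff), V) / span)

    pairwise = [mean_abs(curves[i] - curves[j])
                for i in range(len(curves)) for j in range(i + 1, len(curves))]
    to_diag = [mean_abs(c - V) for c in curves]
    return {
        "mean_pairwise": float(np.mean(pairwise)) if pairwise else float("nan"),
        "mean_to_diagonal": float(np.mean(to_diag)),
    }
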