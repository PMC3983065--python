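"""Empirical spike-threshold measurement from raw voltage traces.

The measured spike threshold is the voltage at the onset of an action
potential, where the onset is the first time before the spike peak at which
dV/dt exceeds a fixed criterion (25 mV/ms by default).  On the (V, dV/dt)
phase plane this corresponds to the voltage at which the trajectory crosses
the criterion line.  Also computed here are the pre-spike statistics used
to characterize threshold variability: the mean membrane potential in a
5 ms window before the onset, the depolarization rate over 1.5 ms before
the onset, and the preceding interspike interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import linregress

from .model import VoltageTrace

__all__ = [
    "MeasuredSpike",
    "detect_spike_onsets",
    "prespike_stats",
    "threshold_correlations",
    "spikes_to_frame",
    "frame_to_spikes",
]

DEFAULT_CRITERION_MV_PER_MS = 25.0
DEFAULT_PROMINENCE_MV = 10.0


@dataclass
class MeasuredSpike:
    """One detected spike with its measured threshold and pre-spike context.

    ``onset_voltage`` is the measured spike threshold (mV).  Statistics that
    cannot be computed (first spike, window overlapping a previous spike or
    the trace start) are ``None``.
    """

    onset_time: float            # ms
    onset_voltage: float         # mV, the measured spike threshold
    peak_time: float             # ms
    peak_voltage: float          # mV
    preceding_isi: Optional[float] = None      # ms
    prespike_mean_V: Optional[float] = None    # mV, 5 ms window
    depol_rate: Optional[float] = None         # mV/ms, 1.5 ms window


def _dvdt(V: np.ndarray, dt: float) -> np.ndarray:
    """Centered finite difference at the recording rate (one-sided at edges)."""
    return np.gradient(V, dt)


def detect_spike_onsets(
    trace: VoltageTrace,
    criterion_mV_per_ms: float = DEFAULT_CRITERION_MV_PER_MS,
    min_peak_prominence_mV: float = DEFAULT_PROMINENCE_MV,
) -> list[MeasuredSpike]:
    """Detect spikes and measure their onset (threshold) voltages.

    Spike peaks are located first (local maxima with at least
    ``min_peak_prominence_mV`` of prominence); for each peak the onset is
    found by scanning backward from the peak for the first sample at which
    dV/dt drops below ``criterion_mV_per_ms`` — the onset is the sample
    just after it, i.e. the start of the suprathreshold-derivative stretch
    leading into the peak.  Peaks sharing an upstroke yield one onset.
    """
    V = trace.samples
    dt = trace.dt
    if V.size < 3:
        return []
    deriv = _dvdt(V, dt)
    peaks, _ = find_peaks(V, prominence=min_peak_prominence_mV)
    out: list[MeasuredSpike] = []
    prev_onset_idx = -1
    prev_peak_idx = 0
    for p in peaks:
        # skip the low-derivative region just below the peak, then walk
        # down the suprathreshold-derivative stretch to its start: the
        # upward crossing of the criterion nearest the peak is the onset
        i = p
        while i > prev_peak_idx and deriv[i] < criterion_mV_per_ms:
            i -= 1
        while i > prev_peak_idx and deriv[i - 1] >= criterion_mV_per_ms:
            i -= 1
        if deriv[i] < criterion_mV_per_ms:
            continue  # no suprathreshold upstroke into this peak
        if i == prev_onset_idx:
            prev_peak_idx = p
            continue  # two peaks on one upstroke
        prev_onset_idx = i
        prev_peak_idx = p
        out.append(MeasuredSpike(
            onset_time=trace.t0 + i * dt,
            onset_voltage=float(V[i]),
            peak_time=trace.t0 + p * dt,
            peak_voltage=float(V[p]),
        ))
    return out


def prespike_stats(
    trace: VoltageTrace,
    spikes: list[MeasuredSpike],
    mean_window_ms: float = 5.0,
    slope_window_ms: float = 1.5,
) -> list[MeasuredSpike]:
    """Fill in pre-spike statistics on a detected spike list (in place).

    Per spike: mean voltage over [onset − mean_window, onset), the
    least-squares depolarization slope over [onset − slope_window, onset),
    and the preceding interspike interval.  A window that reaches past the
    trace start or into the previous spike's waveform leaves the statistic
    undefined (the ISI is kept).
    """
    V = trace.samples
    dt = trace.dt
    for k, sp in enumerate(spikes):
        onset_idx = int(round((sp.onset_time - trace.t0) / dt))
        if k > 0:
            sp.preceding_isi = sp.onset_time - spikes[k - 1].onset_time
        prev_peak_idx = (int(round((spikes[k - 1].peak_time - trace.t0) / dt))
                        if k > 0 else -1)

        for attr, win in (("prespike_mean_V", mean_window_ms),
                          ("depol_rate", slope_window_ms)):
            i0 = onset_idx - int(round(win / dt))
            if i0 < 0 or i0 <= prev_peak_idx:
                continue
            seg = V[i0:onset_idx]
            if seg.size < 2:
                continue
            if attr == "prespike_mean_V":
                sp.prespike_mean_V = float(seg.mean())
            else:
                t = np.arange(seg.size) * dt
                sp.depol_rate = float(linregress(t, seg).slope)
    return spikes


def threshold_correlations(spikes: list[MeasuredSpike]) -> dict:
    """Correlations of measured threshold with its pre-spike predictors.

    Returns Pearson r and OLS slope of onset voltage against the pre-spike
    mean voltage (dimensionless slope), the depolarization rate (slope in
    ms) and the preceding ISI (slope in mV/ms).  Degenerate predictors or a
    constant onset voltage give r = 0 with ``degenerate=True``.
    """
    def _corr(x, y):
        x = np.asarray(x)
        y = np.asarray(y)
        if x.size < 3:
            raise ValueError("need at least 3 spikes with defined statistics")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return 0.0, 0.0, True
        res = linregress(x, y)
        return float(res.rvalue), float(res.slope), False

    pairs = {
        "meanV": [(s.prespike_mean_V, s.onset_voltage) for s in spikes
                  if s.prespike_mean_V is not None],
        "depol": [(s.depol_rate, s.onset_voltage) for s in spikes
                  if s.depol_rate is not None],
        "isi": [(s.preceding_isi, s.onset_voltage) for s in spikes
                if s.preceding_isi is not None],
    }
    out: dict = {"degenerate": False}
    for name, data in pairs.items():
        if len(data) < 3:
            raise ValueError(
                f"need at least 3 spikes with defined {name} statistics")
        x, y = zip(*data)
        r, slope, degen = _corr(x, y)
        out[f"r_{name}"] = r
        out[f"slope_{name}"] = slope
        out["degenerate"] = out["degenerate"] or degen
    # field-convention names
    out["slope_meanV"] = out.pop("slope_meanV", 0.0)
    out["slope_depol_ms"] = out.pop("slope_depol")
    out["slope_isi"] = out.pop("slope_isi")
    return out


_COLUMNS = ["onset_time_ms", "onset_voltage_mV", "peak_time_ms",
            "peak_voltage_mV", "preceding_isi_ms", "prespike_mean_V_mV",
            "depol_rate_mV_per_ms"]


def spikes_to_frame(spikes: list[MeasuredSpike]) -> pd.DataFrame:
    """One row per spike; units in the column names; NaN for undefined."""
    rows = [[s.onset_time, s.onset_voltage, s.peak_time, s.peak_voltage,
             s.preceding_isi, s.prespike_mean_V, s.depol_rate]
            for s in spikes]
    return pd.DataFrame(rows, columns=_COLUMNS, dtype=float)


def frame_to_spikes(df: pd.DataFrame) -> list[MeasuredSpike]:
    out = []
    for _, row in df.iterrows():
        vals = [None if (isinstance(v, float) and math.isnan(v)) else float(v)
                for v in row[_COLUMNS]]
        out.append(MeasuredSpike(*vals))
    return out
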