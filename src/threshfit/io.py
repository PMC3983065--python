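"""Trace, spike-train and parameter persistence.

Two trace formats are supported: a delimited-text format (one voltage per
line, header comments carrying the sampling interval and metadata) and an
HDF5 container (dataset ``V`` in mV with ``dt_ms``/``t0_ms``/``meta``
attributes).  The sampling rate is never guessed: a file without one is
rejected.  Spike trains round-trip as one-column text (ms); manifests and
scores as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .model import SpikeTrain, ThresholdModelParams, VoltageTrace

__all__ = [
    "read_trace", "write_trace",
    "read_spike_train", "write_spike_train",
    "read_params", "write_params",
    "TraceManifest", "ManifestEntry",
]

MANIFEST_VERSION = "1"


def write_trace(path, trace: VoltageTrace, fmt: str | None = None) -> None:
    """Write a voltage trace as text (.csv/.txt) or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "text":
        header = [f"# dt_ms={trace.dt!r}", f"# t0_ms={trace.t0!r}"]
        if trace.meta:
            header.append("# meta=" + json.dumps(trace.meta, sort_keys=True))
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            np.savetxt(fh, trace.samples, fmt="%.6f")
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("V", data=trace.samples)
            d.attrs["dt_ms"] = trace.dt
            d.attrs["t0_ms"] = trace.t0
            d.attrs["meta"] = json.dumps(trace.meta, sort_keys=True)
    else:
        raise ValueError(f"unknown trace format {fmt!r}")


def read_trace(path, fmt: str | None = None) -> VoltageTrace:
    """Read a voltage trace; the sampling interval must be present in the file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "text":
        dt = t0 = None
        meta = {}
        data_lines = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line[1:].strip()
                    if body.startswith("dt_ms="):
                        dt = float(body[len("dt_ms="):])
                    elif body.startswith("t0_ms="):
                        t0 = float(body[len("t0_ms="):])
                    elif body.startswith("meta="):
                        meta = json.loads(body[len("meta="):])
                else:
                    data_lines.append(line)
        if dt is None:
            raise ValueError(f"{path}: no '# dt_ms=' header; sampling "
                             "interval is required, never guessed")
        samples = np.array([float(v) for v in data_lines])
        _check_finite(samples, path)
        return VoltageTrace(samples=samples, dt=dt, t0=t0 or 0.0, meta=meta)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            d = f["V"]
            if "dt_ms" not in d.attrs:
                raise ValueError(f"{path}: missing dt_ms attribute")
            samples = d[:]
            _check_finite(samples, path)
            return VoltageTrace(
                samples=samples, dt=float(d.attrs["dt_ms"]),
                t0=float(d.attrs.get("t0_ms", 0.0)),
                meta=json.loads(d.attrs.get("meta", "{}")))
    raise ValueError(f"unknown trace format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix in (".csv", ".txt", ".dat"):
        return "text"
    raise ValueError(f"cannot infer trace format from suffix {suffix!r}")


def _check_finite(samples: np.ndarray, path) -> None:
    bad = np.flatnonzero(~np.isfinite(samples))
    if bad.size:
        raise ValueError(f"{path}: non-finite samples at indices "
                         f"{bad[:10].tolist()}")


def write_spike_train(path, train: SpikeTrain) -> None:
    with open(path, "w") as fh:
        fh.write(f"# duration_ms={train.duration!r}\n")
        np.savetxt(fh, train.times, fmt="%.6f")


def read_spike_train(path) -> SpikeTrain:
    duration = None
    times = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# duration_ms="):
                duration = float(line[len("# duration_ms="):])
            elif line and not line.startswith("#"):
                times.append(float(line))
    if duration is None:
        duration = (times[-1] + 1.0) if times else 1.0
    return SpikeTrain(times=np.array(times), duration=duration)


def write_params(path, params: ThresholdModelParams) -> None:
    Path(path).write_text(params.to_json() + "\n")


def read_params(path) -> ThresholdModelParams:
    return ThresholdModelParams.from_json(Path(path).read_text())


@dataclass
class ManifestEntry:
    path: str
    format: str            # "text" or "hdf5"
    dt_ms: float
    cell_id: str = ""
    condition: str = ""
    protocol: str = ""


@dataclass
class TraceManifest:
    """List of traces with per-trace metadata; the unit of CLI input."""

    entries: list[ManifestEntry] = field(default_factory=list)
    version: str = MANIFEST_VERSION

    def __post_init__(self):
        ids = [(e.cell_id, e.path) for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate (cell_id, path) entries in manifest")

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({
            "version": self.version,
            "entries": [vars(e) for e in self.entries],
        }, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "TraceManifest":
        d = json.loads(Path(path).read_text())
        return cls(entries=[ManifestEntry(**e) for e in d["entries"]],
                   version=d.get("version", MANIFEST_VERSION))

    def load_traces(self, root=".") -> list[VoltageTrace]:
        root = Path(root)
        traces = []
        for e in self.entries:
            p = Path(e.path)
            if not p.is_absolute():
                p = root / p
            t = read_trace(p, fmt=e.format)
            t.meta.setdefault("cell_id", e.cell_id)
            t.meta.setdefault("condition", e.condition)
            t.meta.setdefault("protocol", e.protocol)
            traces.append(t)
        return traces
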