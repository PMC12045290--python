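"""Ionic-current trace container and tab-separated on-disk format."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Trace", "write_trace_tsv", "read_trace_tsv"]


@dataclass
class Trace:
    """A uniformly sampled ionic-current time series.

    Attributes
    ----------
    dt_s
        Seconds per sample (inverse sampling rate).
    samples_pA
        Current samples in picoamps.
    voltage_mV
        Applied transmembrane voltage.
    meta
        Free-form acquisition metadata (sampling rate, filter cutoff, salt,
        generator seed, ...).
    """

    dt_s: float
    samples_pA: np.ndarray
    voltage_mV: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples_pA = np.asarray(self.samples_pA, dtype=float)
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if not np.all(np.isfinite(self.samples_pA)):
            raise ValueError("trace samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples_pA.size

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.dt_s

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / self.dt_s

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_s


def write_trace_tsv(trace: Trace, path: str | Path) -> None:
    """Write a trace as TSV: '#'-prefixed header lines, then time_s, current_pA."""
    path = Path(path)
    header = dict(trace.meta)
    header.setdefault("voltage_mV", trace.voltage_mV)
    header.setdefault("sampling_rate_hz", trace.sampling_rate_hz)
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}\t{value}\n")
        fh.write("time_s\tcurrent_pA\n")
        t = trace.time_s()
        for ti, ci in zip(t, trace.samples_pA):
            fh.write(f"{ti:.7f}\t{ci:.4f}\n")


def read_trace_tsv(path: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace_tsv`."""
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("\t")
            try:
                meta[key] = float(value) if "." in value or "e" in value.lower() else int(value)
            except ValueError:
                meta[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        data = np.loadtxt(fh, delimiter="\t", skiprows=1, ndmin=2)
    if "sampling_rate_hz" in meta:
        dt = 1.0 / float(meta["sampling_rate_hz"])
    elif data.shape[0] > 1:
        dt = float(data[1, 0] - data[0, 0])
    else:
        raise ValueError("cannot infer sampling rate from trace file")
    return Trace(
        dt_s=dt,
        samples_pA=data[:, 1],
        voltage_mV=float(meta.get("voltage_mV", 0.0)),
        meta=meta,
    )
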