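"""Synthetic data generation.

This module emulates the statistical structure of aerolysin single-channel
recordings of a proline-rich peptide, and of the matching 2D NMR evidence:

* blockade events arrive as a Poisson process whose rate is set by the
  capture rate per micromolar, the peptide concentration and a linear
  voltage factor;
* each capture enters either N-terminus first (populations A = trans and
  B = cis of the Phe2–Pro3 bond, split by the true cis fraction) or
  C-terminus first (population C);
* dwell times are log-normal with a log-median that increases linearly with
  voltage (peptides do not translocate; they back out of the pore);
* normalized blockade levels are Gaussian for A and B and right-skewed
  (log-normal) for C, all within the deep-blockade window;
* the rendered trace is a two-level signal: baseline Gaussian noise around
  the open-pore current I0, and in-event Gaussian noise around
  I0 * (1 - level);
* HSQC-like peak lists carry trans and cis cross-peak volumes for the two
  aromatic sites of Phe2 in proportion to the isomer populations.

Everything is deterministic given (preset, config, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .presets import PeptidePreset, PopulationSpec, SimConfig
from .trace import Trace

__all__ = [
    "EventStream",
    "HSQCPeakList",
    "simulate_event_stream",
    "render_trace",
    "simulate_trace",
    "generate_hsqc",
    "STREAM_COLUMNS",
    "HSQC_COLUMNS",
]

logger = logging.getLogger(__name__)

STREAM_COLUMNS = ["start_s", "duration_s", "population", "level"]
HSQC_COLUMNS = ["shift_H_ppm", "shift_C_ppm", "volume", "isomer_tag", "site"]

#: Chemical shifts (ppm) of the Phe2 aromatic cross peaks used for the
#: synthetic peak lists.  Values are plausible aromatic-region positions;
#: only the volumes carry information for the population estimate.
_HSQC_SHIFTS = {
    ("Cd-Hd", "trans"): (7.28, 129.8),
    ("Cd-Hd", "cis"): (7.22, 129.4),
    ("Ce-He", "trans"): (7.36, 131.2),
    ("Ce-He", "cis"): (7.31, 130.9),
}


@dataclass
class EventStream:
    """Ground-truth blockade events plus bookkeeping from the arrival model."""

    events: pd.DataFrame  # columns STREAM_COLUMNS
    n_dropped: int  # arrivals landing inside a previous event
    voltage_mV: float
    duration_s: float

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class HSQCPeakList:
    """Synthetic HSQC cross-peak list (volumes tagged by isomer and site)."""

    peaks: pd.DataFrame  # columns HSQC_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in HSQC_COLUMNS if c not in self.peaks.columns]
        if missing:
            raise ValueError(f"peak list missing columns {missing}")
        if (self.peaks["volume"] <= 0).any():
            raise ValueError("peak volumes must be positive")


def _draw_levels(spec: PopulationSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw normalized blockade levels for one population."""
    if spec.level_dist == "lognormal":
        # parametrised so the mode equals level_mean and the log-sd equals
        # the coefficient of variation level_sd / level_mean
        s = spec.level_sd / spec.level_mean
        mu = math.log(spec.level_mean) + s * s
        levels = np.exp(rng.normal(mu, s, size=n))
    else:
        levels = rng.normal(spec.level_mean, spec.level_sd, size=n)
    return np.clip(levels, 0.05, 0.999)


def _draw_dwells(
    spec: PopulationSpec, n: int, voltage_mV: float, rng: np.random.Generator
) -> np.ndarray:
    return np.exp(rng.normal(spec.log_median_dwell(voltage_mV), spec.dwell_logsd, size=n))


def simulate_event_stream(preset: PeptidePreset, sim: SimConfig) -> EventStream:
    """Draw a ground-truth event stream for one recording.

    Arrivals follow a Poisson process at the preset's capture rate (scaled
    linearly with voltage about +100 mV).  Each arrival is assigned an entry
    orientation (N- vs C-terminus first) and, for N-terminus captures, an
    isomer (trans -> A, cis -> B) from the true cis fraction.  Arrivals that
    land while a previous event is still blocking the pore are dropped and
    counted — a single pore senses one molecule at a time.
    """
    if sim.duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rate = preset.capture_rate_hz(sim.voltage_mV)
    if rate < 0:
        raise ValueError("capture rate must be non-negative")
    rng = np.random.default_rng(sim.seed)
    empty = pd.DataFrame(columns=STREAM_COLUMNS).astype(
        {"start_s": float, "duration_s": float, "population": object, "level": float}
    )
    if rate == 0:
        return EventStream(empty, 0, sim.voltage_mV, sim.duration_s)

    # draw arrival times in one block sized generously above the expectation
    n_exp = rate * sim.duration_s
    n_draw = int(n_exp + 6.0 * math.sqrt(n_exp) + 16)
    gaps = rng.exponential(1.0 / rate, size=n_draw)
    arrivals = np.cumsum(gaps)
    while arrivals[-1] < sim.duration_s:  # pragma: no cover - rare top-up
        extra = rng.exponential(1.0 / rate, size=n_draw)
        arrivals = np.concatenate([arrivals, arrivals[-1] + np.cumsum(extra)])
    arrivals = arrivals[arrivals < sim.duration_s]
    n = arrivals.size

    # per-arrival attributes drawn up front so kept events are i.i.d.
    is_nterm = rng.random(n) < preset.orientation_split
    is_cis = rng.random(n) < preset.cis_fraction_true
    population = np.where(is_nterm, np.where(is_cis, "B", "A"), "C")

    durations = np.empty(n)
    levels = np.empty(n)
    for label, spec in (("A", preset.pop_A), ("B", preset.pop_B), ("C", preset.pop_C)):
        mask = population == label
        k = int(mask.sum())
        durations[mask] = _draw_dwells(spec, k, sim.voltage_mV, rng)
        levels[mask] = _draw_levels(spec, k, rng)

    # sequential exclusion: the pore is busy until the current event ends
    keep = np.zeros(n, dtype=bool)
    busy_until = -math.inf
    n_dropped = 0
    for i in range(n):
        if arrivals[i] < busy_until:
            n_dropped += 1
            continue
        keep[i] = True
        busy_until = arrivals[i] + durations[i]

    events = pd.DataFrame(
        {
            "start_s": arrivals[keep],
            "duration_s": durations[keep],
            "population": population[keep],
            "level": levels[keep],
        }
    )
    return EventStream(events, n_dropped, sim.voltage_mV, sim.duration_s)


def render_trace(stream: EventStream, sim: SimConfig) -> Trace:
    """Render an event stream into a noisy two-level current trace.

    Baseline samples are Normal(I0, baseline_noise_sd); samples inside an
    event of level L are Normal(I0 * (1 - L), intra_event_noise_sd).  Events
    reaching past the end of the trace are truncated (and logged).  The
    renderer uses its own random stream (seed + 1) so that the same event
    stream can be rendered at different noise settings reproducibly.
    """
    fs = sim.sampling_rate_hz
    n = int(sim.duration_s * fs)
    i0 = sim.open_pore_current_pA
    rng = np.random.default_rng(sim.seed + 1)
    samples = i0 + rng.normal(0.0, sim.baseline_noise_sd_pA, size=n)

    n_truncated = 0
    for start, dur, level in zip(
        stream.events["start_s"], stream.events["duration_s"], stream.events["level"]
    ):
        if start >= sim.duration_s:
            raise ValueError("event starts beyond the end of the trace")
        a = int(round(start * fs))
        b = int(round((start + dur) * fs))
        if b > n:
            b = n
            n_truncated += 1
        if b <= a:
            continue  # sub-sample event, invisible at this sampling rate
        samples[a:b] = i0 * (1.0 - level) + rng.normal(
            0.0, sim.intra_event_noise_sd_pA, size=b - a
        )
    if n_truncated:
        logger.warning("%d event(s) truncated at the end of the trace", n_truncated)

    meta = {
        "voltage_mV": sim.voltage_mV,
        "sampling_rate_hz": fs,
        "filter_cutoff_hz": sim.filter_cutoff_hz,
        "salt": sim.salt,
        "seed": sim.seed,
    }
    return Trace(dt_s=1.0 / fs, samples_pA=samples, voltage_mV=sim.voltage_mV, meta=meta)


def simulate_trace(preset: PeptidePreset, sim: SimConfig) -> tuple[Trace, EventStream]:
    """Convenience: draw an event stream and render it in one call."""
    stream = simulate_event_stream(preset, sim)
    return render_trace(stream, sim), stream


def generate_hsqc(
    preset: PeptidePreset, volume_noise_cv: float = 0.02, seed: int = 0
) -> HSQCPeakList:
    """Generate a synthetic HSQC peak list for one peptide.

    For each aromatic site of Phe2 (Cd-Hd and Ce-He) the trans peak volume is
    proportional to (1 - cis_fraction_true) and the cis peak volume to
    cis_fraction_true, each multiplied by an independent Normal(1, cv)
    factor truncated to positive values.  Peaks of an absent isomer
    (fraction exactly 0 or 1) are omitted.
    """
    if volume_noise_cv < 0:
        raise ValueError("volume_noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    fractions = {"trans": preset.trans_fraction_true, "cis": preset.cis_fraction_true}
    for site in ("Cd-Hd", "Ce-He"):
        for isomer, frac in fractions.items():
            if frac <= 0:
                continue
            factor = rng.normal(1.0, volume_noise_cv)
            while factor <= 0:  # pragma: no cover - cv would have to be huge
                factor = rng.normal(1.0, volume_noise_cv)
            h_ppm, c_ppm = _HSQC_SHIFTS[(site, isomer)]
            rows.append(
                {
                    "shift_H_ppm": h_ppm,
                    "shift_C_ppm": c_ppm,
                    "volume": frac * factor,
                    "isomer_tag": isomer,
                    "site": site,
                }
            )
    return HSQCPeakList(pd.DataFrame(rows, columns=HSQC_COLUMNS))
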