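"""Blockade-event detection and selection.

Turns an ionic-current trace into a table of resistive-pulse events with the
features used downstream: the dwell time Tt, the normalized blockade level
dIb = (I0_local - Ib) / I0_local, and the intra-event current noise.

Detection is threshold-based: an event is a maximal run of samples below
``threshold_frac * I0``; runs separated by fewer than ``min_gap_samples``
baseline samples are merged (tolerating single-sample noise spikes).  Event
features are computed from interior samples only, trimming ``edge_trim``
samples at each boundary to avoid rise-time bias, and the local open-pore
current is estimated from flanking baseline windows so that slow baseline
drift does not corrupt the normalized level.

Event selection follows fixed criteria: dwell time between 200 us and 1 s,
normalized blockade level inside a per-voltage amplitude window, and
intra-event noise between 1 and 100 pA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace import Trace

__all__ = [
    "EventRecord",
    "FilterCriteria",
    "EVENT_COLUMNS",
    "estimate_baseline",
    "detect_events",
    "filter_events",
    "event_frequency",
]

#: Column order of event tables (the on-disk CSV adds kept / reject_reason /
#: population at the end).
EVENT_COLUMNS = [
    "start_idx",
    "end_idx",
    "start_s",
    "end_s",
    "Tt_s",
    "I0_pA",
    "Ib_pA",
    "dIb_norm",
    "noise_pA",
]


@dataclass(frozen=True)
class EventRecord:
    """One blockade event; indices are half-open [start_idx, end_idx)."""

    start_idx: int
    end_idx: int
    Tt_s: float
    I0_local_pA: float
    Ib_pA: float
    dIb_norm: float
    noise_pA: float
    population: str | None = None


@dataclass(frozen=True)
class FilterCriteria:
    """Event-selection window.

    Defaults: blockade duration from 200 us to 1 s, intra-event noise from
    1 pA to 100 pA, and a normalized-amplitude window of [0.5, 0.95] (the
    per-voltage amplitude window; override per recording condition).
    """

    min_dwell_s: float = 200e-6
    max_dwell_s: float = 1.0
    dIb_min: float = 0.5
    dIb_max: float = 0.95
    noise_min_pA: float = 1.0
    noise_max_pA: float = 100.0

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.min_dwell_s, self.max_dwell_s, "dwell"),
            (self.dIb_min, self.dIb_max, "dIb"),
            (self.noise_min_pA, self.noise_max_pA, "noise"),
        ):
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be below upper bound")


def estimate_baseline(
    trace: Trace,
    exclusion_frac: float = 0.75,
    max_iter: int = 20,
) -> tuple[float, float]:
    """Robust open-pore current and baseline noise estimate.

    Iteratively takes the median of samples not attributable to blockades
    (samples below ``exclusion_frac`` of the current I0 estimate are
    excluded) until the estimate stabilises.  The scale is a Gaussian-
    consistent MAD of the retained samples.

    Raises
    ------
    ValueError
        If fewer than 1000 samples are available, if more than 90% of
        samples end up excluded, or if no positive baseline can be found.
    """
    x = trace.samples_pA
    if x.size < 1000:
        raise ValueError("baseline estimation needs at least 1000 samples")
    i0 = float(np.median(x))
    retained = x
    for _ in range(max_iter):
        if i0 <= 0:
            raise ValueError("no stable baseline: non-positive current estimate")
        mask = x >= exclusion_frac * i0
        if mask.sum() < 0.1 * x.size:
            raise ValueError("no stable baseline: >90% of samples excluded")
        retained = x[mask]
        new_i0 = float(np.median(retained))
        if abs(new_i0 - i0) <= 1e-9 * max(abs(i0), 1.0):
            i0 = new_i0
            break
        i0 = new_i0
    if i0 <= 0:
        raise ValueError("no stable baseline: non-positive current estimate")
    mad = float(np.median(np.abs(retained - i0)))
    return i0, 1.4826 * mad


def _runs_below(below: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end indices (half-open) of maximal runs of True."""
    padded = np.concatenate(([False], below, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return edges[0::2], edges[1::2]


def detect_events(
    trace: Trace,
    threshold_frac: float = 0.5,
    min_gap_samples: int = 5,
    edge_trim: int = 2,
    flank_window_s: float = 5e-3,
    baseline: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Detect blockade events by threshold crossing.

    Parameters
    ----------
    trace
        The current trace to segment.
    threshold_frac
        Detection threshold as a fraction of the open-pore current; a sample
        belongs to a blockade when its current is below
        ``threshold_frac * I0``.
    min_gap_samples
        Runs separated by fewer than this many baseline samples are merged.
    edge_trim
        Samples dropped at each event boundary before computing the mean
        in-event current and noise (events too short to trim use all their
        samples).
    flank_window_s
        Width of the baseline windows flanking each event used for the local
        open-pore current; windows are clipped at neighbouring events and
        fall back to the global estimate when empty.
    baseline
        Optional precomputed ``(I0_pA, baseline_sd_pA)``; estimated from the
        trace when omitted.

    Returns
    -------
    pandas.DataFrame
        One row per event with columns :data:`EVENT_COLUMNS`; empty (with
        columns) if no threshold crossing occurs.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie strictly between 0 and 1")
    i0_global, _ = baseline if baseline is not None else estimate_baseline(trace)
    x = trace.samples_pA
    below = x < threshold_frac * i0_global
    starts, ends = _runs_below(below)
    if starts.size == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)

    # merge runs separated by short baseline gaps
    if starts.size > 1 and min_gap_samples > 0:
        gaps = starts[1:] - ends[:-1]
        keep_boundary = gaps >= min_gap_samples
        starts = np.concatenate(([starts[0]], starts[1:][keep_boundary]))
        ends = np.concatenate((ends[:-1][keep_boundary], [ends[-1]]))

    w = max(int(round(flank_window_s / trace.dt_s)), 1)
    dt = trace.dt_s
    rows = []
    for k in range(starts.size):
        s, e = int(starts[k]), int(ends[k])
        interior = x[s + edge_trim : e - edge_trim] if e - s > 2 * edge_trim + 1 else x[s:e]
        ib = float(interior.mean())
        noise = float(interior.std(ddof=1)) if interior.size > 1 else 0.0

        prev_end = int(ends[k - 1]) if k > 0 else 0
        next_start = int(starts[k + 1]) if k + 1 < starts.size else x.size
        left = x[max(s - w, prev_end) : s]
        right = x[e : min(e + w, next_start)]
        if left.size + right.size > 0:
            i0_local = float((left.sum() + right.sum()) / (left.size + right.size))
        else:
            i0_local = i0_global
        rows.append(
            (
                s,
                e,
                s * dt,
                e * dt,
                (e - s) * dt,
                i0_local,
                ib,
                (i0_local - ib) / i0_local,
                noise,
            )
        )
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df["start_idx"] = df["start_idx"].astype(int)
    df["end_idx"] = df["end_idx"].astype(int)
    return df


def filter_events(
    events: pd.DataFrame, criteria: FilterCriteria | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an event table into kept and rejected events.

    An event is kept iff its dwell time lies in [min_dwell, max_dwell), its
    normalized blockade level in [dIb_min, dIb_max], and its intra-event
    noise in [noise_min, noise_max].  Rejected events carry the first
    failing criterion (checked in the order duration, amplitude, noise) in a
    ``reject_reason`` column.  Filtering is idempotent: re-filtering the
    kept table changes nothing.
    """
    c = criteria or FilterCriteria()
    if events.empty:
        rejected = events.copy()
        rejected["reject_reason"] = pd.Series(dtype=object)
        return events.copy(), rejected

    ok_dwell = (events["Tt_s"] >= c.min_dwell_s) & (events["Tt_s"] < c.max_dwell_s)
    ok_amp = (events["dIb_norm"] >= c.dIb_min) & (events["dIb_norm"] <= c.dIb_max)
    ok_noise = (events["noise_pA"] >= c.noise_min_pA) & (events["noise_pA"] <= c.noise_max_pA)
    keep = ok_dwell & ok_amp & ok_noise

    kept = events[keep].reset_index(drop=True)
    rejected = events[~keep].reset_index(drop=True)
    reason = np.select(
        [~ok_dwell[~keep].to_numpy(), ~ok_amp[~keep].to_numpy()],
        ["duration", "amplitude"],
        default="noise",
    )
    rejected = rejected.assign(reject_reason=reason)
    return kept, rejected


def event_frequency(
    events: pd.DataFrame,
    trace_duration_s: float,
    by: str | None = None,
) -> float | pd.Series:
    """Event rate in events per second.

    With ``by`` set to a column name (``"population"`` or ``"orientation"``)
    returns a per-group Series instead of the total rate.
    """
    if trace_duration_s <= 0:
        raise ValueError("trace_duration_s must be positive")
    if by is None:
        return len(events) / trace_duration_s
    if by not in events.columns:
        raise KeyError(f"events table has no column {by!r}")
    return events.groupby(by, observed=True).size() / trace_duration_s
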