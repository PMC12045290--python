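"""Residence-time kinetics, entry-orientation assignment, and voltage scans.

Populations A and B overlap in blockade level and share the N-terminus-first
entry orientation, so they are merged ("AB") for residence-time statistics;
population C (C-terminus-first entry) is analysed separately and dwells
longer.  A voltage scan runs the full detection -> selection -> mixture-fit
-> assignment pipeline at each voltage and summarises mean residence time
and interaction frequency per group, flagging whether the mean residence
time is non-decreasing with voltage — the signature that the peptide does
not translocate but eventually exits against the driving force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import FilterCriteria, detect_events, event_frequency, filter_events
from .fitting import MixtureFit, MixtureModel, build_histogram, fit_mixture
from .trace import Trace

__all__ = [
    "ORIENTATION_OF",
    "VoltageScanResult",
    "assign_population",
    "mean_residence_time",
    "dwell_lognormal_fit",
    "block_statistic",
    "voltage_scan",
]

#: Entry orientation implied by each blockade population.
ORIENTATION_OF = {"A": "N-terminus", "B": "N-terminus", "C": "C-terminus"}

_GROUP_LABELS = {"AB": ("A", "B"), "C": ("C",)}


def assign_population(events: pd.DataFrame, model: MixtureModel | MixtureFit) -> pd.DataFrame:
    """Label each event A, B or C by maximum component responsibility.

    The responsibility of a component at an event's normalized level is its
    fitted curve value (height times peak-normalized shape).  Ties break
    deterministically to the component with the lower location.  Returns a
    copy with ``population`` and ``orientation`` columns (A and B map to
    N-terminus-first entry, C to C-terminus-first).
    """
    m = model.model if isinstance(model, MixtureFit) else model
    out = events.copy()
    if out.empty:
        out["population"] = pd.Series(dtype=object)
        out["orientation"] = pd.Series(dtype=object)
        return out
    x = out["dIb_norm"].to_numpy(dtype=float)
    comps = sorted(m.components().items(), key=lambda kv: kv[1].location)
    labels = [k for k, _ in comps]
    resp = np.stack([c.height * c.shape(x) for _, c in comps])
    # argmax returns the first maximum, i.e. the lower-location component on ties
    winner = np.argmax(resp, axis=0)
    out["population"] = np.asarray(labels, dtype=object)[winner]
    out["orientation"] = out["population"].map(ORIENTATION_OF)
    return out


def _group_dwells(events: pd.DataFrame, group: str) -> np.ndarray:
    if group not in _GROUP_LABELS:
        raise ValueError(f"group must be one of {sorted(_GROUP_LABELS)}, got {group!r}")
    if "population" not in events.columns:
        raise KeyError("events must carry a 'population' column; run assign_population")
    mask = events["population"].isin(_GROUP_LABELS[group])
    return events.loc[mask, "Tt_s"].to_numpy(dtype=float)


def mean_residence_time(events: pd.DataFrame, group: str = "AB") -> tuple[float, float]:
    """Arithmetic mean and standard deviation of dwell times in a group.

    ``group`` is ``"AB"`` (the merged overlapping populations) or ``"C"``.
    Raises if the group holds fewer than 2 events.
    """
    t = _group_dwells(events, group)
    if t.size < 2:
        raise ValueError(f"group {group!r} has fewer than 2 events")
    return float(t.mean()), float(t.std(ddof=1))


def dwell_lognormal_fit(events: pd.DataFrame, group: str = "AB") -> tuple[float, float]:
    """Log-normal dwell fit for a group: (median_s, logsd)."""
    t = _group_dwells(events, group)
    if t.size < 2:
        raise ValueError(f"group {group!r} has fewer than 2 events")
    logt = np.log(t)
    return float(math.exp(logt.mean())), float(logt.std(ddof=1))


def block_statistic(
    values: np.ndarray,
    n_blocks: int = 3,
    rng: np.random.Generator | None = None,
    statistic=np.mean,
) -> tuple[float, float]:
    """Mean and spread of a statistic over random equal blocks.

    Emulates replicate experiments by splitting the pooled events into
    ``n_blocks`` random blocks, computing the statistic per block, and
    reporting the mean and standard deviation across blocks.
    """
    values = np.asarray(values, dtype=float)
    if values.size < n_blocks:
        raise ValueError("not enough values to form the requested blocks")
    rng = rng or np.random.default_rng(0)
    perm = rng.permutation(values.size)
    blocks = np.array_split(values[perm], n_blocks)
    stats = np.array([statistic(b) for b in blocks])
    return float(stats.mean()), float(stats.std(ddof=1))


@dataclass
class VoltageScanResult:
    """Per-voltage kinetics summary.

    ``summary`` has one row per (voltage, group) with the block-averaged
    mean residence time, its spread across blocks, the interaction frequency
    of the corresponding entry orientation, and the event count.
    ``monotone_AB`` / ``monotone_C`` flag whether the mean residence time is
    non-decreasing across the voltage grid within one pooled standard error
    per step.  Voltages with no kept events are listed in
    ``empty_voltages``.
    """

    summary: pd.DataFrame
    monotone_AB: bool
    monotone_C: bool
    empty_voltages: list = field(default_factory=list)

    def flags(self) -> dict:
        return {
            "monotone_AB": self.monotone_AB,
            "monotone_C": self.monotone_C,
            "empty_voltages": list(self.empty_voltages),
        }


def _monotone_within_se(means: np.ndarray, ses: np.ndarray) -> bool:
    """Non-decreasing sequence, allowing one pooled standard error per step."""
    for i in range(means.size - 1):
        tol = math.sqrt(ses[i] ** 2 + ses[i + 1] ** 2)
        if means[i + 1] < means[i] - tol:
            return False
    return True


def voltage_scan(
    traces: dict[float, Trace],
    threshold_frac: float = 0.5,
    criteria: FilterCriteria | None = None,
    n_bins: int = 100,
    n_blocks: int = 3,
    seed: int = 0,
) -> VoltageScanResult:
    """Run the event pipeline at each voltage and summarise the kinetics.

    ``traces`` maps applied voltage (mV) to the recorded trace.  Each trace
    is segmented, filtered, histogram-fitted and population-labeled; groups
    AB and C are then summarised by the 3-block replicate statistic.
    """
    if len(traces) < 2:
        raise ValueError("voltage scan needs at least 2 voltages")
    rows = []
    empty: list[float] = []
    rng = np.random.default_rng(seed)
    for voltage in sorted(traces):
        trace = traces[voltage]
        events = detect_events(trace, threshold_frac=threshold_frac)
        kept, _ = filter_events(events, criteria)
        if kept.empty:
            empty.append(voltage)
            continue
        fit = fit_mixture(build_histogram(kept, n_bins=n_bins))
        labeled = assign_population(kept, fit)
        freq = event_frequency(labeled, trace.duration_s, by="orientation")
        for group, orientation in (("AB", "N-terminus"), ("C", "C-terminus")):
            dwells = _group_dwells(labeled, group)
            if dwells.size >= n_blocks:
                mean_tt, sd_tt = block_statistic(dwells, n_blocks=n_blocks, rng=rng)
            elif dwells.size >= 2:
                mean_tt, sd_tt = float(dwells.mean()), float(dwells.std(ddof=1))
            else:
                mean_tt, sd_tt = float("nan"), float("nan")
            rows.append(
                {
                    "voltage_mV": voltage,
                    "group": group,
                    "mean_Tt_s": mean_tt,
                    "sd_Tt_s": sd_tt,
                    "frequency_hz": float(freq.get(ORIENTATION_OF[group[0]], 0.0)),
                    "n_events": int(dwells.size),
                }
            )
    summary = pd.DataFrame(
        rows,
        columns=["voltage_mV", "group", "mean_Tt_s", "sd_Tt_s", "frequency_hz", "n_events"],
    )

    def _flag(group: str) -> bool:
        sub = summary[(summary["group"] == group) & summary["mean_Tt_s"].notna()]
        sub = sub.sort_values("voltage_mV")
        if len(sub) < 2:
            return True
        ses = sub["sd_Tt_s"].to_numpy() / np.sqrt(n_blocks)
        return _monotone_within_se(sub["mean_Tt_s"].to_numpy(), ses)

    return VoltageScanResult(
        summary=summary,
        monotone_AB=_flag("AB"),
        monotone_C=_flag("C"),
        empty_voltages=empty,
    )
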