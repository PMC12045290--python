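"""Event detection against per-sample oracles, and the selection rules."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prolinopore import (
    FilterCriteria,
    Trace,
    detect_events,
    estimate_baseline,
    event_frequency,
    filter_events,
)
from tests.conftest import match_to_truth


def make_trace(samples, dt=1e-4, voltage=100.0):
    return Trace(dt_s=dt, samples_pA=np.asarray(samples, dtype=float), voltage_mV=voltage)


def oracle_detect(samples, threshold, min_gap):
    """Brute-force per-sample threshold classifier with gap merging."""
    below = [x < threshold for x in samples]
    runs = []
    i = 0
    while i < len(below):
        if below[i]:
            j = i
            while j < len(below) and below[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < min_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return merged


# --- baseline -------------------------------------------------------------


def test_baseline_of_constant_trace():
    i0, sd = estimate_baseline(make_trace(np.full(5000, 250.0)))
    assert i0 == pytest.approx(250.0)
    assert sd == pytest.approx(0.0)


def test_baseline_ignores_blockade_samples():
    x = np.full(10000, 250.0)
    x[1000:2000] = 50.0  # 10% of the time in a deep blockade
    i0, sd = estimate_baseline(make_trace(x))
    assert i0 == pytest.approx(250.0)


def test_baseline_all_zero_trace_errors():
    with pytest.raises(ValueError, match="baseline"):
        estimate_baseline(make_trace(np.zeros(5000)))


def test_baseline_requires_enough_samples():
    with pytest.raises(ValueError):
        estimate_baseline(make_trace(np.full(10, 250.0)))


# --- detection ------------------------------------------------------------


def test_flat_trace_has_no_events():
    events = detect_events(make_trace(np.full(5000, 250.0)))
    assert events.empty
    assert list(events.columns)  # schema present even when empty


def test_noiseless_rectangle_recovers_dwell_and_level_exactly():
    # 100 pA baseline, one 1.0 ms dip to 20 pA at 10 kHz sampling
    x = np.full(5000, 100.0)
    x[2000:2010] = 20.0
    events = detect_events(make_trace(x, dt=1e-4))
    assert len(events) == 1
    ev = events.iloc[0]
    assert ev.Tt_s == pytest.approx(1.0e-3)
    assert ev.dIb_norm == pytest.approx(0.8, abs=1e-12)
    assert ev.noise_pA == pytest.approx(0.0)


def test_two_dips_match_per_sample_oracle():
    x = np.full(20000, 100.0)
    x[5000:5005] = 20.0  # 0.5 ms at 10 kHz
    x[9000:9020] = 30.0  # 2.0 ms
    events = detect_events(make_trace(x, dt=1e-4), threshold_frac=0.5, min_gap_samples=5)
    expected = oracle_detect(x, 50.0, 5)
    assert len(events) == len(expected) == 2
    for (s, e), (_, row) in zip(expected, events.iterrows()):
        assert (row.start_idx, row.end_idx) == (s, e)
        assert row.Tt_s == pytest.approx((e - s) * 1e-4)


def test_close_dips_are_merged_below_min_gap():
    x = np.full(8000, 100.0)
    x[3000:3010] = 20.0
    x[3012:3020] = 20.0  # 2-sample gap < min_gap_samples=5
    events = detect_events(make_trace(x, dt=1e-4), min_gap_samples=5)
    assert len(events) == 1
    assert events.iloc[0].start_idx == 3000 and events.iloc[0].end_idx == 3020


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.data())
def test_detection_equals_oracle_on_random_two_level_traces(data):
    """On noiseless two-level traces, detection reproduces the per-sample
    threshold classifier exactly for any threshold between the two levels."""
    n = 4000
    n_events = data.draw(st.integers(0, 6))
    level_frac = data.draw(st.floats(0.6, 0.9))
    # threshold strictly between the blockade fraction (<= 0.4) and baseline
    threshold_frac = data.draw(st.floats(0.45, 0.55))
    x = np.full(n, 200.0)
    pos = 500
    placed = []
    for _ in range(n_events):
        width = data.draw(st.integers(1, 60))
        gap = data.draw(st.integers(6, 400))  # keep runs separated > min_gap
        pos += gap
        if pos + width >= n - 10:
            break
        x[pos : pos + width] = 200.0 * (1 - level_frac)
        placed.append((pos, pos + width))
        pos += width
    events = detect_events(make_trace(x, dt=1e-4), threshold_frac=threshold_frac)
    expected = oracle_detect(x, threshold_frac * 200.0, 5)
    assert len(events) == len(expected) == len(placed)
    assert [(r.start_idx, r.end_idx) for r in events.itertuples()] == [
        tuple(run) for run in expected
    ]


# --- filtering ------------------------------------------------------------


def _event_row(Tt=1e-3, dIb=0.8, noise=5.0):
    return {
        "start_idx": 0, "end_idx": 10, "start_s": 0.0, "end_s": Tt,
        "Tt_s": Tt, "I0_pA": 250.0, "Ib_pA": 250.0 * (1 - dIb),
        "dIb_norm": dIb, "noise_pA": noise,
    }


@pytest.mark.parametrize(
    "row, reason",
    [
        (_event_row(Tt=100e-6), "duration"),  # below the 200 us floor
        (_event_row(Tt=1.5), "duration"),  # above the 1 s ceiling
        (_event_row(noise=0.5), "noise"),  # below the 1 pA noise floor
        (_event_row(noise=150.0), "noise"),
        (_event_row(dIb=0.3), "amplitude"),  # outside the amplitude window
    ],
)
def test_selection_rejects_with_first_failing_criterion(row, reason):
    kept, rejected = filter_events(pd.DataFrame([row]))
    assert kept.empty
    assert rejected.iloc[0].reject_reason == reason


def test_selection_keeps_events_inside_all_windows():
    kept, rejected = filter_events(pd.DataFrame([_event_row()]))
    assert len(kept) == 1 and rejected.empty


def test_selection_of_empty_table():
    kept, rejected = filter_events(pd.DataFrame(columns=list(_event_row())))
    assert kept.empty and rejected.empty


def test_selection_is_idempotent(wt_sim_medium):
    trace, _, _ = wt_sim_medium
    events = detect_events(trace)
    kept, _ = filter_events(events)
    kept2, rejected2 = filter_events(kept)
    assert rejected2.empty
    pd.testing.assert_frame_equal(kept, kept2)


def test_invalid_criteria_rejected():
    with pytest.raises(ValueError):
        FilterCriteria(min_dwell_s=1.0, max_dwell_s=0.5)


# --- frequency ------------------------------------------------------------


def test_event_frequency_basic():
    df = pd.DataFrame([_event_row()] * 100)
    assert event_frequency(df, 50.0) == pytest.approx(2.0)
    assert event_frequency(df.iloc[:0], 50.0) == 0.0
    with pytest.raises(ValueError):
        event_frequency(df, 0.0)


def test_recovered_frequency_within_poisson_bound(wt_sim_medium, wt_preset):
    trace, stream, sim = wt_sim_medium
    events = detect_events(trace)
    rate = wt_preset.capture_rate_hz(100.0)
    expected = rate * sim.duration_s
    assert abs(len(events) - expected) <= 3 * math.sqrt(expected) + stream.n_dropped


# --- end-to-end recovery --------------------------------------------------


def test_generated_events_recovered_with_small_level_error(wt_sim_medium):
    """>= 95% of comfortably-sized generated events are detected with a
    level error below twice the normalized intra-event noise."""
    trace, stream, sim = wt_sim_medium
    events = detect_events(trace)
    kept, _ = filter_events(events)
    gt = stream.events
    target = gt[(gt.duration_s >= 400e-6) & (gt.duration_s <= 0.5)]
    matched = match_to_truth(kept, stream)
    dt = trace.dt_s
    hits = 0
    tol = 2 * sim.intra_event_noise_sd_pA / sim.open_pore_current_pA
    starts = matched["true_start_s"].to_numpy()
    errs = (matched["dIb_norm"] - matched["true_level"]).to_numpy()
    for t0, lvl in zip(target["start_s"], target["level"]):
        j = np.argmin(np.abs(starts - t0))
        if abs(starts[j] - t0) <= 2 * dt and abs(errs[j]) < tol:
            hits += 1
    assert hits / len(target) >= 0.95
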