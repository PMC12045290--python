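"""Generator statistics: arrivals, dwell laws, population weights, HSQC lists."""

import math

import numpy as np
import pytest
from scipy import stats

from prolinopore import (
    PeptidePreset,
    SimConfig,
    generate_hsqc,
    get_preset,
    render_trace,
    simulate_event_stream,
)
from prolinopore.presets import _default_populations


def _rate_preset(rate_hz_per_uM, conc=1.0, cis=0.34):
    a, b, c = _default_populations()
    return PeptidePreset(
        name="WT", cis_fraction_true=cis, pop_A=a, pop_B=b, pop_C=c,
        capture_rate_hz_per_uM=rate_hz_per_uM, concentration_uM=conc,
    )


def test_zero_capture_rate_gives_empty_stream():
    stream = simulate_event_stream(_rate_preset(0.0), SimConfig(duration_s=50.0, seed=1))
    assert stream.n_events == 0
    assert stream.n_dropped == 0


def test_same_seed_gives_identical_stream_and_trace(wt_preset):
    sim = SimConfig(duration_s=5.0, seed=123)
    s1 = simulate_event_stream(wt_preset, sim)
    s2 = simulate_event_stream(wt_preset, sim)
    assert s1.events.equals(s2.events)
    t1 = render_trace(s1, sim)
    t2 = render_trace(s2, sim)
    np.testing.assert_array_equal(t1.samples_pA, t2.samples_pA)


def test_arrival_count_matches_poisson_expectation():
    # rate 2 Hz for 500 s: arrivals (kept + dropped) within 3 sigma of 1000
    stream = simulate_event_stream(_rate_preset(2.0), SimConfig(duration_s=500.0, seed=3))
    total = stream.n_events + stream.n_dropped
    assert abs(total - 1000) <= 3 * math.sqrt(1000)


def test_invalid_duration_rejected(wt_preset):
    with pytest.raises(ValueError):
        SimConfig(duration_s=0.0)


def test_dwell_times_are_lognormal_at_generating_parameters(wt_preset):
    # high event count at fixed voltage; KS of log dwell against the
    # generating normal law at alpha = 0.01
    sim = SimConfig(duration_s=700.0, seed=5)
    stream = simulate_event_stream(wt_preset, sim)
    nterm = stream.events[stream.events["population"].isin(["A", "B"])]
    assert len(nterm) >= 5000
    logt = np.log(nterm["duration_s"].to_numpy())
    spec = wt_preset.pop_A
    ks = stats.kstest(logt, "norm", args=(spec.log_median_dwell(100.0), spec.dwell_logsd))
    assert ks.pvalue > 0.01


def test_mean_dwell_strictly_increases_with_voltage(wt_preset):
    means = []
    for v in (70, 80, 90, 100, 110, 120):
        # capture rate scales with voltage; stretch duration to keep n high
        sim = SimConfig(voltage_mV=v, duration_s=700.0 * 100.0 / v, seed=40 + v)
        stream = simulate_event_stream(wt_preset, sim)
        nterm = stream.events[stream.events["population"].isin(["A", "B"])]
        assert len(nterm) > 4000
        means.append(nterm["duration_s"].mean())
    assert all(m2 > m1 for m1, m2 in zip(means, means[1:]))


def test_cis_label_fraction_matches_truth_within_binomial_bound(wt_preset):
    stream = simulate_event_stream(wt_preset, SimConfig(duration_s=700.0, seed=9))
    nterm = stream.events[stream.events["population"].isin(["A", "B"])]
    n = len(nterm)
    frac_b = (nterm["population"] == "B").mean()
    p = wt_preset.cis_fraction_true
    assert abs(frac_b - p) <= 3 * math.sqrt(p * (1 - p) / n)


def test_event_levels_lie_in_unit_interval(wt_preset):
    stream = simulate_event_stream(wt_preset, SimConfig(duration_s=100.0, seed=2))
    levels = stream.events["level"]
    assert ((levels > 0) & (levels < 1)).all()


# --- trace rendering ------------------------------------------------------


def test_empty_stream_renders_pure_baseline(wt_preset):
    sim = SimConfig(duration_s=2.0, seed=8)
    stream = simulate_event_stream(_rate_preset(0.0), sim)
    trace = render_trace(stream, sim)
    assert trace.n_samples == int(sim.duration_s * sim.sampling_rate_hz)
    n = trace.n_samples
    assert abs(trace.samples_pA.mean() - sim.open_pore_current_pA) <= (
        3 * sim.baseline_noise_sd_pA / math.sqrt(n)
    )


def test_noiseless_rectangle_renders_exact_levels():
    import pandas as pd

    from prolinopore.synthetic import EventStream

    sim = SimConfig(
        duration_s=0.1, seed=1, baseline_noise_sd_pA=0.0, intra_event_noise_sd_pA=0.0,
        I0_pA=250.0,
    )
    events = pd.DataFrame(
        {"start_s": [0.04], "duration_s": [0.01], "population": ["A"], "level": [0.8]}
    )
    trace = render_trace(EventStream(events, 0, 100.0, 0.1), sim)
    fs = sim.sampling_rate_hz
    inside = trace.samples_pA[int(0.04 * fs) : int(0.05 * fs)]
    np.testing.assert_allclose(inside, 50.0)
    outside = np.concatenate(
        [trace.samples_pA[: int(0.04 * fs)], trace.samples_pA[int(0.05 * fs) :]]
    )
    np.testing.assert_allclose(outside, 250.0)


def test_rendered_blockade_time_matches_summed_durations(wt_preset):
    # fraction of samples below threshold ~ summed event durations, within
    # one sample per event boundary
    sim = SimConfig(duration_s=20.0, seed=21, baseline_noise_sd_pA=0.0,
                    intra_event_noise_sd_pA=0.0)
    stream = simulate_event_stream(wt_preset, sim)
    trace = render_trace(stream, sim)
    below = (trace.samples_pA < 0.5 * sim.open_pore_current_pA).sum()
    ends = np.minimum(stream.events["start_s"] + stream.events["duration_s"], sim.duration_s)
    expected = ((ends - stream.events["start_s"]) * sim.sampling_rate_hz).sum()
    assert abs(below - expected) <= len(stream.events)


# --- HSQC peak lists ------------------------------------------------------


def test_hsqc_equal_populations_give_equal_volumes():
    a, b, c = _default_populations()
    preset = PeptidePreset(name="WT", cis_fraction_true=0.5, pop_A=a, pop_B=b, pop_C=c)
    peaks = generate_hsqc(preset, volume_noise_cv=0.0, seed=1).peaks
    for site, grp in peaks.groupby("site"):
        vols = grp.set_index("isomer_tag")["volume"]
        assert vols["trans"] == pytest.approx(vols["cis"])


def test_hsqc_pure_trans_omits_cis_peaks():
    a, b, c = _default_populations()
    preset = PeptidePreset(name="WT", cis_fraction_true=0.0, pop_A=a, pop_B=b, pop_C=c)
    peaks = generate_hsqc(preset, volume_noise_cv=0.0, seed=1).peaks
    assert (peaks["isomer_tag"] == "cis").sum() == 0
    assert set(peaks["site"]) == {"Cd-Hd", "Ce-He"}


def test_hsqc_volume_ratio_converges_to_true_cis_fraction(wt_preset):
    fracs = []
    for seed in range(200):
        peaks = generate_hsqc(wt_preset, volume_noise_cv=0.02, seed=seed).peaks
        sums = peaks.groupby("isomer_tag")["volume"].sum()
        fracs.append(sums["cis"] / (sums["cis"] + sums["trans"]))
    # Monte-Carlo mean of the integrated fraction converges to the truth
    assert np.mean(fracs) == pytest.approx(wt_preset.cis_fraction_true, abs=0.005)


def test_hsqc_negative_cv_rejected(wt_preset):
    with pytest.raises(ValueError):
        generate_hsqc(wt_preset, volume_noise_cv=-0.1, seed=0)
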