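import numpy as np
import pytest

from prolinopore import (
    SimConfig,
    analyze_peptide,
    get_preset,
    simulate_condition,
)


@pytest.fixture(scope="session")
def wt_preset():
    return get_preset("WT")


@pytest.fixture(scope="session")
def wt_medium():
    """One medium-size WT analysis shared by fitting/kinetics tests."""
    return analyze_peptide("WT", voltage_mV=100.0, n_events_target=1500, seed=11)


@pytest.fixture(scope="session")
def wt_sim_medium(wt_preset):
    """A medium WT recording with its ground-truth stream, for recovery checks."""
    trace, stream, sim = simulate_condition(wt_preset, 100.0, 1200, seed=7)
    return trace, stream, sim


def match_to_truth(kept, stream):
    """Attach ground-truth population/level to detected events by nearest start."""
    gts = stream.events["start_s"].to_numpy()
    ks = kept["start_s"].to_numpy()
    pos = np.searchsorted(gts, ks)
    left = np.clip(pos - 1, 0, len(gts) - 1)
    right = np.clip(pos, 0, len(gts) - 1)
    idx = np.where(np.abs(gts[left] - ks) < np.abs(gts[right] - ks), left, right)
    out = kept.copy()
    out["true_pop"] = stream.events["population"].to_numpy()[idx]
    out["true_level"] = stream.events["level"].to_numpy()[idx]
    out["true_start_s"] = gts[idx]
    return out
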