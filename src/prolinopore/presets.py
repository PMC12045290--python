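"""Peptide presets and simulation configuration.

A :class:`PeptidePreset` is the ground truth the synthetic generator draws
from: the true cis fraction of the Phe2–Pro3 peptide bond, the three blockade
populations (A = trans and B = cis for N-terminus-first captures, C for
C-terminus-first captures), the capture kinetics, and the peptide
concentration.  The three built-in presets correspond to the wild-type
proline peptide (``WT``), the 4-(S)-fluoroproline variant (``S4F``, cis
equilibrium shifted up) and the 4-(R)-fluoroproline variant (``R4F``, cis
equilibrium shifted down); their true cis fractions are the NMR peak-integral
estimates for those peptides (34%, 43%, 22%).

Units: currents in pA, times in seconds, voltages in mV, concentrations in
micromolar.  All dwell parameters are stated at the reference voltage
(+100 mV).
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = [
    "PopulationSpec",
    "PeptidePreset",
    "SimConfig",
    "DEFAULT_PRESETS",
    "get_preset",
    "load_presets_toml",
    "dump_presets_toml",
    "REFERENCE_VOLTAGE_MV",
    "OPEN_PORE_CONDUCTANCE_NS",
    "open_pore_current_pA",
]

#: Voltage at which dwell medians and capture rates are specified.
REFERENCE_VOLTAGE_MV = 100.0

#: Ohmic open-pore conductance in 4 M KCl (nS); I0 = G * V.
OPEN_PORE_CONDUCTANCE_NS = 2.5


def open_pore_current_pA(voltage_mV: float) -> float:
    """Ohmic open-pore current: I0 [pA] = G [nS] * V [mV]."""
    return OPEN_PORE_CONDUCTANCE_NS * voltage_mV


@dataclass(frozen=True)
class PopulationSpec:
    """One blockade population (A, B or C).

    Parameters
    ----------
    label
        Population label, one of ``"A"``, ``"B"``, ``"C"``.
    level_mean
        Central normalized blockade level dIb = (I0 - Ib)/I0, in (0, 1).
        For the default presets all three populations sit in the 0.7–0.9
        window characteristic of deep peptide blockades of aerolysin.
    level_sd
        Spread of the normalized level.
    level_dist
        ``"normal"`` for symmetric populations (A, B) or ``"lognormal"`` for
        the right-skewed C population.  The log-normal is parametrised so
        that its mode equals ``level_mean`` and its coefficient of variation
        equals ``level_sd / level_mean``.
    dwell_logmean_s
        Natural log of the median dwell time (s) at the reference voltage.
    dwell_logsd
        Log-scale spread of the dwell distribution (dimensionless).
    dwell_voltage_slope
        Per-mV additive slope on the log-median dwell.  Positive values make
        residence times lengthen with voltage — the no-translocation
        signature of peptides that back out of the pore instead of
        translocating through it.
    """

    label: str
    level_mean: float
    level_sd: float
    dwell_logmean_s: float
    dwell_logsd: float
    dwell_voltage_slope: float = 0.01
    level_dist: str = "normal"

    def __post_init__(self) -> None:
        if self.label not in ("A", "B", "C"):
            raise ValueError(f"population label must be A, B or C, got {self.label!r}")
        if not 0.0 < self.level_mean < 1.0:
            raise ValueError("level_mean must lie in (0, 1)")
        if self.level_sd <= 0:
            raise ValueError("level_sd must be positive")
        if self.level_dist not in ("normal", "lognormal"):
            raise ValueError(f"unknown level_dist {self.level_dist!r}")

    def log_median_dwell(self, voltage_mV: float) -> float:
        """Log median dwell (s) at a given voltage."""
        return self.dwell_logmean_s + self.dwell_voltage_slope * (
            voltage_mV - REFERENCE_VOLTAGE_MV
        )

    def mean_dwell_s(self, voltage_mV: float) -> float:
        """Analytic mean of the log-normal dwell distribution."""
        return math.exp(self.log_median_dwell(voltage_mV) + 0.5 * self.dwell_logsd**2)


@dataclass(frozen=True)
class PeptidePreset:
    """Generator ground truth for one peptide / condition."""

    name: str
    cis_fraction_true: float
    pop_A: PopulationSpec
    pop_B: PopulationSpec
    pop_C: PopulationSpec
    orientation_split: float = 0.70  # fraction of captures entering N-terminus first
    capture_rate_hz_per_uM: float = 0.70
    concentration_uM: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cis_fraction_true <= 1.0:
            raise ValueError("cis_fraction_true must lie in [0, 1]")
        if not 0.0 < self.orientation_split < 1.0:
            raise ValueError("orientation_split must lie in (0, 1)")
        if self.capture_rate_hz_per_uM < 0 or self.concentration_uM < 0:
            raise ValueError("capture rate and concentration must be non-negative")

    def capture_rate_hz(self, voltage_mV: float = REFERENCE_VOLTAGE_MV) -> float:
        """Total capture rate (Hz) with a linear voltage scaling about +100 mV."""
        return (
            self.capture_rate_hz_per_uM
            * self.concentration_uM
            * max(voltage_mV / REFERENCE_VOLTAGE_MV, 0.0)
        )

    @property
    def trans_fraction_true(self) -> float:
        return 1.0 - self.cis_fraction_true


@dataclass(frozen=True)
class SimConfig:
    """Acquisition settings for a synthetic recording."""

    voltage_mV: float = 100.0
    I0_pA: float | None = None  # ohmic default G*V when None
    baseline_noise_sd_pA: float = 4.0
    intra_event_noise_sd_pA: float = 5.0
    sampling_rate_hz: float = 50_000.0
    filter_cutoff_hz: float = 5_000.0  # metadata only; no digital filter applied
    duration_s: float = 10.0
    seed: int = 0
    salt: str = "4 M KCl"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.voltage_mV > 0 and self.open_pore_current_pA <= 0:
            raise ValueError("I0_pA must be positive at positive voltage")

    @property
    def open_pore_current_pA(self) -> float:
        if self.I0_pA is not None:
            return self.I0_pA
        return open_pore_current_pA(self.voltage_mV)

    @property
    def dt_s(self) -> float:
        return 1.0 / self.sampling_rate_hz


def _default_populations() -> tuple[PopulationSpec, PopulationSpec, PopulationSpec]:
    # A and B overlap partially (0.78 vs 0.82, shared sd) and share the dwell
    # law (same entry orientation); C is distinct, right-skewed and slower.
    pop_a = PopulationSpec(
        label="A",
        level_mean=0.78,
        level_sd=0.015,
        dwell_logmean_s=math.log(1.0e-3),
        dwell_logsd=1.0,
        dwell_voltage_slope=0.01,
    )
    pop_b = PopulationSpec(
        label="B",
        level_mean=0.82,
        level_sd=0.015,
        dwell_logmean_s=math.log(1.0e-3),
        dwell_logsd=1.0,
        dwell_voltage_slope=0.01,
    )
    pop_c = PopulationSpec(
        label="C",
        level_mean=0.88,
        level_sd=0.02,
        dwell_logmean_s=math.log(3.0e-3),
        dwell_logsd=1.0,
        dwell_voltage_slope=0.01,
        level_dist="lognormal",
    )
    return pop_a, pop_b, pop_c


def _make_preset(name: str, cis_fraction: float, concentration_uM: float) -> PeptidePreset:
    pop_a, pop_b, pop_c = _default_populations()
    return PeptidePreset(
        name=name,
        cis_fraction_true=cis_fraction,
        pop_A=pop_a,
        pop_B=pop_b,
        pop_C=pop_c,
        concentration_uM=concentration_uM,
    )


#: Built-in presets.  True cis fractions are the NMR integral estimates for
#: the three peptides; concentrations follow the nanopore recordings
#: (WT and the 4S variant at 15 uM, the 4R variant at 10 uM).
DEFAULT_PRESETS: dict[str, PeptidePreset] = {
    "WT": _make_preset("WT", 0.34, 15.0),
    "S4F": _make_preset("S4F", 0.43, 15.0),
    "R4F": _make_preset("R4F", 0.22, 10.0),
}


def get_preset(name: str) -> PeptidePreset:
    """Look up a built-in preset by name (case-insensitive)."""
    key = name.upper()
    if key not in DEFAULT_PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(DEFAULT_PRESETS)}"
        )
    return DEFAULT_PRESETS[key]


# ---------------------------------------------------------------------------
# TOML round-trip for preset configuration files
# ---------------------------------------------------------------------------

_POP_KEYS = (
    "label",
    "level_mean",
    "level_sd",
    "dwell_logmean_s",
    "dwell_logsd",
    "dwell_voltage_slope",
    "level_dist",
)


def load_presets_toml(path: str | Path) -> dict[str, PeptidePreset]:
    """Read peptide presets from a TOML file (one table per peptide)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    presets: dict[str, PeptidePreset] = {}
    for name, tab in raw.items():
        pops = {}
        for key in ("pop_A", "pop_B", "pop_C"):
            pops[key] = PopulationSpec(**{k: tab[key][k] for k in _POP_KEYS if k in tab[key]})
        presets[name] = PeptidePreset(
            name=name,
            cis_fraction_true=tab["cis_fraction_true"],
            orientation_split=tab.get("orientation_split", 0.70),
            capture_rate_hz_per_uM=tab.get("capture_rate_hz_per_uM", 0.70),
            concentration_uM=tab.get("concentration_uM", 15.0),
            **pops,
        )
    return presets


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace('"', '\\"') + '"'


def dump_presets_toml(presets: dict[str, PeptidePreset], path: str | Path) -> None:
    """Write presets to a TOML file readable by :func:`load_presets_toml`."""
    lines: list[str] = []
    for name, preset in presets.items():
        lines.append(f"[{name}]")
        d = asdict(preset)
        for key in ("cis_fraction_true", "orientation_split",
                    "capture_rate_hz_per_uM", "concentration_uM"):
            lines.append(f"{key} = {_toml_value(d[key])}")
        for pop_key in ("pop_A", "pop_B", "pop_C"):
            lines.append(f"[{name}.{pop_key}]")
            for k in _POP_KEYS:
                lines.append(f"{k} = {_toml_value(d[pop_key][k])}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
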