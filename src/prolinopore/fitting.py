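"""Blockade-level histogram, mixture model, and the trans/cis ratio statistic.

The normalized blockade-level histogram of a peptide recording shows three
populations: two partially overlapping Gaussian peaks A (trans) and B (cis)
from N-terminus-first captures, and a right-skewed log-normal peak C from
C-terminus-first captures.  The histogram (counts scaled so the tallest bin
is 1) is fitted with the sum of two Gaussians and a log-normal, each
expressed as a peak-normalized shape times a height, so a fitted height is
directly the component's amplitude on the normalized-count scale.

The conformer split is the ratio statistic a / (a + b): with a the height of
population A rescaled to 1 and b the height of population B on the same
scale, the trans percentage is 100 / (1 + b).  When A and B have equal
widths, component heights are proportional to event counts and b/(1 + b)
estimates the cis fraction among N-terminus captures; the fit therefore
shares the A/B width by default (overridable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks

__all__ = [
    "BlockadeHistogram",
    "GaussComponent",
    "LogNormComponent",
    "MixtureModel",
    "MixtureFit",
    "PopulationRatio",
    "build_histogram",
    "fit_mixture",
    "count_populations",
    "trans_cis_ratio",
]


@dataclass
class BlockadeHistogram:
    """Histogram of normalized blockade level, max bin scaled to 1."""

    bin_edges: np.ndarray
    counts_norm: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts_norm = np.asarray(self.counts_norm, dtype=float)
        if self.bin_edges.size != self.counts_norm.size + 1:
            raise ValueError("bin_edges must have one more entry than counts")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dIb_norm": self.centers, "counts_norm": self.counts_norm})


def build_histogram(events, n_bins: int = 100) -> BlockadeHistogram:
    """Histogram the normalized blockade levels of kept events over [0, 1].

    ``events`` may be an event table (uses its ``dIb_norm`` column) or a
    plain array of normalized levels.  Counts are divided by the maximum bin
    count so the tallest bin equals 1.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be at least 10")
    values = np.asarray(
        events["dIb_norm"] if isinstance(events, pd.DataFrame) else events, dtype=float
    )
    if values.size == 0:
        raise ValueError("no events to histogram")
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    return BlockadeHistogram(edges, counts / counts.max())


# ---------------------------------------------------------------------------
# mixture model
# ---------------------------------------------------------------------------


@dataclass
class GaussComponent:
    mu: float
    sigma: float
    height: float

    def shape(self, x: np.ndarray) -> np.ndarray:
        """Peak-normalized Gaussian (value 1 at mu)."""
        z = (np.asarray(x, dtype=float) - self.mu) / self.sigma
        return np.exp(-0.5 * z * z)

    @property
    def location(self) -> float:
        return self.mu


@dataclass
class LogNormComponent:
    logmu: float
    logsigma: float
    height: float

    @property
    def mode(self) -> float:
        return math.exp(self.logmu - self.logsigma**2)

    @property
    def location(self) -> float:
        return self.mode

    def shape(self, x: np.ndarray) -> np.ndarray:
        """Log-normal density rescaled so its value at the mode is 1."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        pos = x > 0
        lx = np.log(x[pos])
        s2 = self.logsigma**2
        # log pdf(x) - log pdf(mode), with pdf the standard log-normal density
        out[pos] = np.exp(
            -((lx - self.logmu) ** 2) / (2 * s2) - lx + self.logmu - 0.5 * s2
        )
        return out


@dataclass
class MixtureModel:
    """Two Gaussians (A, B) plus one log-normal (C) over normalized level.

    Heights are peak amplitudes on the normalized-count scale.  The label
    convention orders locations: mu_A < mu_B < mode(C).
    """

    gauss_A: GaussComponent
    gauss_B: GaussComponent
    lognorm_C: LogNormComponent

    def components(self) -> dict[str, GaussComponent | LogNormComponent]:
        return {"A": self.gauss_A, "B": self.gauss_B, "C": self.lognorm_C}

    def curve(self, x: np.ndarray) -> np.ndarray:
        return sum(c.height * c.shape(x) for c in self.components().values())

    def component_curves(self, x: np.ndarray) -> dict[str, np.ndarray]:
        return {k: c.height * c.shape(x) for k, c in self.components().items()}

    def heights(self) -> dict[str, float]:
        return {k: c.height for k, c in self.components().items()}

    def to_dict(self) -> dict:
        return {
            "gauss_A": {"mu": self.gauss_A.mu, "sigma": self.gauss_A.sigma,
                        "height": self.gauss_A.height},
            "gauss_B": {"mu": self.gauss_B.mu, "sigma": self.gauss_B.sigma,
                        "height": self.gauss_B.height},
            "lognorm_C": {"logmu": self.lognorm_C.logmu,
                          "logsigma": self.lognorm_C.logsigma,
                          "height": self.lognorm_C.height,
                          "mode": self.lognorm_C.mode},
        }


@dataclass
class MixtureFit:
    """A fitted mixture with diagnostics."""

    model: MixtureModel
    residual_norm: float
    converged: bool
    n_bins: int
    message: str = ""

    def __getattr__(self, name):  # delegate component access to the model
        return getattr(self.model, name)


def _auto_init(hist: BlockadeHistogram) -> tuple[float, float, float, float, float, float]:
    """Initial (muA, hA, muB, hB, modeC, hC) from histogram peaks."""
    counts = hist.counts_norm
    centers = hist.centers
    width = float(np.mean(np.diff(hist.bin_edges)))
    idx, _ = find_peaks(counts, prominence=0.04)
    if idx.size >= 3:
        c_idx = idx[-1]
        rest = idx[:-1]
        top2 = rest[np.argsort(counts[rest])[-2:]]
        a_idx, b_idx = sorted(top2)
        return (
            centers[a_idx], counts[a_idx],
            centers[b_idx], counts[b_idx],
            centers[c_idx], counts[c_idx],
        )
    if idx.size == 2:
        a_idx, c_idx = idx
        return (
            centers[a_idx], counts[a_idx],
            centers[a_idx] + 3 * width, 0.3 * counts[a_idx],
            centers[c_idx], counts[c_idx],
        )
    if idx.size == 1:
        a_idx = idx[0]
    else:
        a_idx = int(np.argmax(counts))
    mu_a = centers[a_idx]
    return (mu_a, counts[a_idx], mu_a + 3 * width, 0.05, mu_a + 8 * width, 0.05)


def fit_mixture(
    hist: BlockadeHistogram,
    init: MixtureModel | None = None,
    share_sigma_ab: bool = True,
    max_nfev: int = 20_000,
) -> MixtureFit:
    """Least-squares fit of the bi-Gaussian + log-normal model to a histogram.

    Components are peak-normalized shapes times heights, fitted to the
    normalized counts.  Initialisation is automatic from histogram peaks
    unless ``init`` is given.  With ``share_sigma_ab`` (default) the two
    Gaussians share a single width, which makes their fitted heights
    proportional to their event counts — the property the a/(a+b) ratio
    statistic relies on.

    Non-convergence is reported through the ``converged`` flag, not raised.
    After fitting, labels are reassigned so mu_A < mu_B.
    """
    occupied = int(np.count_nonzero(hist.counts_norm))
    if occupied < 3:
        raise ValueError("histogram is degenerate: fewer than 3 occupied bins")
    x = hist.centers
    y = hist.counts_norm

    if init is not None:
        mu_a, h_a = init.gauss_A.mu, init.gauss_A.height
        mu_b, h_b = init.gauss_B.mu, init.gauss_B.height
        mode_c, h_c = init.lognorm_C.mode, init.lognorm_C.height
        s_a, s_b = init.gauss_A.sigma, init.gauss_B.sigma
        ls_c = init.lognorm_C.logsigma
    else:
        mu_a, h_a, mu_b, h_b, mode_c, h_c = _auto_init(hist)
        s_a = s_b = 0.015
        ls_c = 0.03

    def unpack(p):
        if share_sigma_ab:
            h_a, mu_a, h_b, mu_b, s_ab, h_c, lmu, ls = p
            s_a_, s_b_ = s_ab, s_ab
        else:
            h_a, mu_a, s_a_, h_b, mu_b, s_b_, h_c, lmu, ls = p
        return (
            GaussComponent(mu_a, s_a_, h_a),
            GaussComponent(mu_b, s_b_, h_b),
            LogNormComponent(lmu, ls, h_c),
        )

    lmu0 = math.log(mode_c) + ls_c**2
    if share_sigma_ab:
        p0 = [h_a, mu_a, h_b, mu_b, s_a, h_c, lmu0, ls_c]
        lo = [0.0, 0.05, 0.0, 0.05, 1e-3, 0.0, math.log(0.05), 5e-3]
        hi = [2.0, 1.0, 2.0, 1.0, 0.2, 2.0, math.log(1.5), 0.6]
    else:
        p0 = [h_a, mu_a, s_a, h_b, mu_b, s_b, h_c, lmu0, ls_c]
        lo = [0.0, 0.05, 1e-3, 0.0, 0.05, 1e-3, 0.0, math.log(0.05), 5e-3]
        hi = [2.0, 1.0, 0.2, 2.0, 1.0, 0.2, 2.0, math.log(1.5), 0.6]
    p0 = np.clip(p0, lo, hi)

    def residuals(p):
        a, b, c = unpack(p)
        return a.height * a.shape(x) + b.height * b.shape(x) + c.height * c.shape(x) - y

    res = least_squares(residuals, p0, bounds=(lo, hi), max_nfev=max_nfev)
    comp_a, comp_b, comp_c = unpack(res.x)
    if comp_a.mu > comp_b.mu:  # enforce the ascending-location label convention
        comp_a, comp_b = (
            GaussComponent(comp_b.mu, comp_b.sigma, comp_b.height),
            GaussComponent(comp_a.mu, comp_a.sigma, comp_a.height),
        )
    model = MixtureModel(comp_a, comp_b, comp_c)
    return MixtureFit(
        model=model,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.status > 0),
        n_bins=y.size,
        message=res.message,
    )


def count_populations(model: MixtureModel | MixtureFit, height_floor: float = 0.05) -> int:
    """Number of mixture components with height at or above ``height_floor``."""
    m = model.model if isinstance(model, MixtureFit) else model
    return sum(1 for c in m.components().values() if c.height >= height_floor)


# ---------------------------------------------------------------------------
# the trans/cis ratio statistic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationRatio:
    """The a/(a+b) conformer split: a = 1 is the height of population A."""

    a: float
    b: float
    trans_pct: float
    cis_pct: float

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "trans_pct": self.trans_pct,
                "cis_pct": self.cis_pct}


def trans_cis_ratio(model: MixtureModel | MixtureFit) -> PopulationRatio:
    """Compute the trans/cis split from the fitted A and B heights.

    Heights are rescaled so a = 1; then trans% = 100 * a / (a + b) and
    cis% = 100 - trans%.  Raises if population A is absent (zero height).
    """
    m = model.model if isinstance(model, MixtureFit) else model
    h_a = m.gauss_A.height
    if h_a <= 0:
        raise ValueError("population A absent: cannot form the a/(a+b) ratio")
    b = m.gauss_B.height / h_a
    trans_pct = 100.0 / (1.0 + b)
    return PopulationRatio(a=1.0, b=b, trans_pct=trans_pct, cis_pct=100.0 - trans_pct)
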