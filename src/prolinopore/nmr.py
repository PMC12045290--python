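"""Cis-fraction estimation from HSQC cross-peak integrals.

The aromatic protons of the residue preceding the proline resonate at
distinct positions for the trans and cis amide isomers, so the respective
cross-peak integrals of the two aromatic sites (Cd-Hd and Ce-He) report the
conformer populations directly.  The estimator here is semi-quantitative:
volumes are summed per isomer across both sites, and the cis percentage is
100 * cis / (cis + trans).  It is invariant under uniform rescaling of all
volumes and serves as the independent cross-check of the nanopore ratio
statistic.
"""

from __future__ import annotations

from .synthetic import HSQCPeakList

__all__ = ["REQUIRED_SITES", "integrate_sites", "cis_fraction"]

REQUIRED_SITES = ("Cd-Hd", "Ce-He")


def integrate_sites(peaks: HSQCPeakList) -> dict[str, float]:
    """Sum peak volumes per isomer across the two aromatic sites.

    Raises
    ------
    ValueError
        If either required site is missing from the peak list (named in the
        message).
    """
    df = peaks.peaks
    present = set(df["site"].unique())
    for site in REQUIRED_SITES:
        if site not in present:
            raise ValueError(f"peak list is missing site {site!r}")
    sums = df.groupby("isomer_tag", observed=True)["volume"].sum()
    return {"trans": float(sums.get("trans", 0.0)), "cis": float(sums.get("cis", 0.0))}


def cis_fraction(volumes: dict[str, float]) -> float:
    """Cis-isomer percentage, 100 * cis / (cis + trans)."""
    trans = float(volumes.get("trans", 0.0))
    cis = float(volumes.get("cis", 0.0))
    total = trans + cis
    if total <= 0:
        raise ValueError("total integrated volume is zero")
    return 100.0 * cis / total
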