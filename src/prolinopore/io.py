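"""On-disk formats: event tables, ground-truth streams, peak lists, histograms.

All formats are plain text with fixed, documented column orders so that
every pipeline stage can be re-run from saved intermediates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .detection import EVENT_COLUMNS
from .fitting import BlockadeHistogram
from .synthetic import HSQC_COLUMNS, STREAM_COLUMNS, EventStream, HSQCPeakList

__all__ = [
    "EVENT_TABLE_COLUMNS",
    "write_events_csv",
    "read_events_csv",
    "write_stream_csv",
    "read_stream_csv",
    "write_hsqc_csv",
    "read_hsqc_csv",
    "write_histogram_tsv",
    "read_histogram_tsv",
]

#: Full on-disk event-table column order.
EVENT_TABLE_COLUMNS = EVENT_COLUMNS + ["kept", "reject_reason", "population"]


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event table with the fixed column order.

    Missing bookkeeping columns (``kept``, ``reject_reason``,
    ``population``) are added empty/true so detection output, filter output
    and labeled tables all share one schema.
    """
    df = events.copy()
    if "kept" not in df.columns:
        df["kept"] = True
    if "reject_reason" not in df.columns:
        df["reject_reason"] = ""
    if "population" not in df.columns:
        df["population"] = ""
    df = df.reindex(columns=EVENT_TABLE_COLUMNS)
    df.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    for col in ("reject_reason", "population"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df


def write_stream_csv(stream: EventStream, path: str | Path) -> None:
    stream.events.reindex(columns=STREAM_COLUMNS).to_csv(path, index=False)


def read_stream_csv(path: str | Path, voltage_mV: float = 100.0,
                    duration_s: float | None = None) -> EventStream:
    df = pd.read_csv(path)
    if duration_s is None:
        duration_s = float((df["start_s"] + df["duration_s"]).max()) if len(df) else 0.0
    return EventStream(df.reindex(columns=STREAM_COLUMNS), n_dropped=0,
                       voltage_mV=voltage_mV, duration_s=duration_s)


def write_hsqc_csv(peaks: HSQCPeakList, path: str | Path) -> None:
    peaks.peaks.reindex(columns=HSQC_COLUMNS).to_csv(path, index=False)


def read_hsqc_csv(path: str | Path) -> HSQCPeakList:
    return HSQCPeakList(pd.read_csv(path).reindex(columns=HSQC_COLUMNS))


def write_histogram_tsv(hist: BlockadeHistogram, path: str | Path) -> None:
    hist.to_frame().to_csv(path, sep="\t", index=False)


def read_histogram_tsv(path: str | Path) -> BlockadeHistogram:
    df = pd.read_csv(path, sep="\t")
    centers = df["dIb_norm"].to_numpy()
    width = centers[1] - centers[0]
    edges = list(centers - width / 2) + [centers[-1] + width / 2]
    return BlockadeHistogram(edges, df["counts_norm"].to_numpy())
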