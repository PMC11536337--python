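"""Raven-style selection table I/O (tab-separated, one row per selection)."""

from __future__ import annotations

from typing import List

import pandas as pd

from .detect import CallSelection

__all__ = ["read_selection_table", "write_selection_table",
           "selections_to_frame", "frame_to_selections",
           "MANDATORY_COLUMNS"]

MANDATORY_COLUMNS = ("Selection", "View", "Channel", "Begin Time (s)",
                     "End Time (s)", "Low Freq (Hz)", "High Freq (Hz)")


class SelectionTableError(ValueError):
    """Raised for malformed selection tables."""


def selections_to_frame(selections: List[CallSelection]) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(selections, start=1):
        rows.append({
            "Selection": i, "View": "Spectrogram 1", "Channel": 1,
            "Begin Time (s)": s.begin, "End Time (s)": s.end,
            "Low Freq (Hz)": s.low_freq, "High Freq (Hz)": s.high_freq,
        })
    return pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS))


def frame_to_selections(df: pd.DataFrame,
                        recording_id: str = "rec") -> List[CallSelection]:
    sels = []
    for i in range(len(df)):
        sels.append(CallSelection(
            begin=float(df["Begin Time (s)"].iloc[i]),
            end=float(df["End Time (s)"].iloc[i]),
            low_freq=float(df["Low Freq (Hz)"].iloc[i]),
            high_freq=float(df["High Freq (Hz)"].iloc[i]),
            recording_id=recording_id, index=i))
    return sels


def write_selection_table(table, path) -> None:
    """Write selections (list of CallSelection or a DataFrame) as a Raven
    tab-separated table.  Extra columns in a DataFrame are preserved."""
    if not isinstance(table, pd.DataFrame):
        table = selections_to_frame(table)
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise SelectionTableError(f"missing mandatory columns: {missing}")
    table.to_csv(path, sep="\t", index=False, float_format="%.9f")


def read_selection_table(path) -> pd.DataFrame:
    """Read a Raven selection table; unknown columns are kept as-is."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SelectionTableError(
            f"{path!r} is not a Raven selection table; "
            f"missing mandatory columns: {missing}")
    for col in ("Begin Time (s)", "End Time (s)",
                "Low Freq (Hz)", "High Freq (Hz)"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise SelectionTableError(
                f"column {col!r} is not numeric; comma decimal separators "
                "are not supported")
    return df
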