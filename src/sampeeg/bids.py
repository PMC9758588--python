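"""Optional adapter for BIDS-EEG events tables.

Maps sample-level events TSVs (one row per drawn sample) from a BIDS-style
directory tree onto the internal event-table layout used by the epoch
analyses. This is a reader for the deposited dataset's layout; no analysis
depends on it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .epochs import EVENT_COLUMNS

__all__ = ["load_bids_events", "events_to_tsv", "events_from_tsv"]

REQUIRED_COLUMNS = ("onset", "value", "side", "trial")


def events_from_tsv(path) -> pd.DataFrame:
    """Read one events TSV, validating the required columns."""
    table = pd.read_csv(path, sep="\t")
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"events table {path} is missing required column '{col}'")
    return table


def events_to_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def load_bids_events(root) -> pd.DataFrame:
    """Collect all ``sub-*/eeg/*_events.tsv`` tables under a BIDS root.

    Returns one concatenated sample-event table with a ``participant`` column
    derived from the subject directory name.
    """
    root = Path(root)
    paths = sorted(root.glob("sub-*/eeg/*_events.tsv"))
    if not paths:
        raise ValueError(f"no events TSVs found under {root} (expected sub-*/eeg/*_events.tsv)")
    frames = []
    for p in paths:
        table = events_from_tsv(p)
        sub = p.parts[-3]
        table = table.copy()
        table["participant"] = int(sub.split("-")[1]) if sub.split("-")[1].isdigit() else sub
        frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    ordered = [c for c in EVENT_COLUMNS if c in out.columns]
    rest = [c for c in out.columns if c not in ordered]
    return out[ordered + rest]
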