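"""Plain-text IO for event logs, dyad-year tables and run configuration."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "write_event_log",
    "read_event_log",
    "write_dyad_year_table",
    "read_dyad_year_table",
    "load_config",
]


def write_event_log(events: pd.DataFrame, path) -> None:
    """Event log CSV: ISO-8601 date, winner, loser (plus year if present)."""
    out = events.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_event_log(path) -> pd.DataFrame:
    events = pd.read_csv(path)
    events["date"] = pd.to_datetime(events["date"])
    if not events["date"].is_monotonic_increasing:
        raise ValueError("event log must be time-ordered")
    return events


def write_dyad_year_table(table: pd.DataFrame, path) -> None:
    cols = ["sender", "receiver", "year", "behaviour", "count", "effort_hours"]
    table[cols].to_csv(path, index=False)


def read_dyad_year_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if (table["effort_hours"] <= 0).any():
        raise ValueError("effort_hours must be positive")
    return table


def load_config(path) -> dict:
    """YAML or JSON run configuration; must carry an explicit ``seed``."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    if "seed" not in cfg:
        raise ValueError("config must set an explicit seed")
    return cfg
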