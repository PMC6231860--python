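"""Local-time conversion and hour-of-day / day-of-week sentiment profiles.

Post timestamps arrive in UTC; diurnal analysis needs the poster's local
clock.  Each state maps to its dominant (most-populous) IANA timezone in an
editable data file, and conversion is DST-aware through the zone database.
Profiles bin POSITIVE/NEGATIVE posts by local hour (0-23) or ISO weekday
(Monday first) and report the negative fraction neg/(pos+neg) per bin,
undefined (NaN) for empty bins.
"""

from __future__ import annotations

import csv
from datetime import datetime, timezone
from typing import Iterable, Optional
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from ._data import data_path
from .sentiment import NEGATIVE, POSITIVE

HOUR = "HOUR"
WEEKDAY = "WEEKDAY"

WEEKDAY_NAMES = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]


class StateTimezoneMap:
    """State code -> IANA timezone name (dominant zone per state)."""

    def __init__(self, mapping: dict[str, str]):
        self.mapping = dict(mapping)

    @classmethod
    def default(cls) -> "StateTimezoneMap":
        with open(data_path("state_timezones.csv"), encoding="utf-8") as fh:
            mapping = {row["state"]: row["timezone"] for row in csv.DictReader(fh)}
        return cls(mapping)

    @classmethod
    def from_csv(cls, path) -> "StateTimezoneMap":
        with open(path, encoding="utf-8") as fh:
            return cls({row["state"]: row["timezone"] for row in csv.DictReader(fh)})

    def zone(self, state: str) -> ZoneInfo:
        if state not in self.mapping:
            raise KeyError(f"no timezone mapped for state {state!r}")
        return ZoneInfo(self.mapping[state])


def to_local(ts_utc: datetime, state: str, tzmap: Optional[StateTimezoneMap] = None) -> datetime:
    """Convert a UTC timestamp to the state's local time (DST-aware)."""
    tzmap = tzmap or StateTimezoneMap.default()
    if ts_utc.tzinfo is None:
        ts_utc = ts_utc.replace(tzinfo=timezone.utc)
    return ts_utc.astimezone(tzmap.zone(state))


def profile(records: Iterable[tuple[datetime, str]], axis: str = HOUR) -> pd.DataFrame:
    """Temporal profile over (local timestamp, polarity) pairs.

    Neutral posts must be excluded upstream; any passed in are ignored.
    Returns a DataFrame indexed by bin with columns pos, neg, fraction.
    """
    if axis not in (HOUR, WEEKDAY):
        raise ValueError(f"unknown axis {axis!r}")
    n_bins = 24 if axis == HOUR else 7
    pos = np.zeros(n_bins, dtype=int)
    neg = np.zeros(n_bins, dtype=int)
    for ts_local, polarity in records:
        if polarity == POSITIVE:
            counts = pos
        elif polarity == NEGATIVE:
            counts = neg
        else:
            continue
        b = ts_local.hour if axis == HOUR else ts_local.weekday()
        counts[b] += 1
    total = pos + neg
    with np.errstate(invalid="ignore"):
        fraction = np.where(total > 0, neg / np.maximum(total, 1), np.nan)
    index = pd.Index(
        range(24) if axis == HOUR else WEEKDAY_NAMES,
        name="hour" if axis == HOUR else "weekday",
    )
    return pd.DataFrame({"pos": pos, "neg": neg, "fraction": fraction}, index=index)
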