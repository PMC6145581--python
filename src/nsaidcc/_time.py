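"""Calendar helpers.

All internal arithmetic is done on whole days represented as integer day
numbers (days since 1970-01-01).  Intervals are closed on both ends.  CSV
interfaces use ISO-8601 date strings.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25


def day(date_like) -> int:
    """Integer day number of a date given as ISO string, date, or Timestamp."""
    if isinstance(date_like, (int, np.integer)):
        return int(date_like)
    ts = pd.Timestamp(date_like)
    return int(ts.to_datetime64().astype("datetime64[D]").astype(np.int64))


def to_date(d: int) -> _dt.date:
    return (_dt.date(1970, 1, 1) + _dt.timedelta(days=int(d)))


def to_iso(d: int) -> str:
    return to_date(d).isoformat()


def days_col(series: pd.Series) -> np.ndarray:
    """Parse a column of ISO dates (or datetimes) into int64 day numbers."""
    dt = pd.to_datetime(series, format="ISO8601")
    return dt.to_numpy().astype("datetime64[D]").astype(np.int64)


def iso_col(days: np.ndarray) -> pd.Series:
    return pd.Series(np.asarray(days, dtype=np.int64).astype("datetime64[D]").astype(str))


def age_years(at_day, birth_day) -> np.ndarray:
    """Fractional age in years at a given day (vectorised)."""
    return (np.asarray(at_day, dtype=np.float64) - np.asarray(birth_day, dtype=np.float64)) / DAYS_PER_YEAR
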