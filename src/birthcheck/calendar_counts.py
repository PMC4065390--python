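"""Parsing of person-level birthdate records and aggregation to daily counts.

The modelled object throughout the package is a dense daily series: for every
calendar day ``d`` between the first and last observed birthdate, the number
``N(d)`` of individuals in the register born on that day, together with a
binary indicator marking weekends (and, optionally, public holidays), which
the intensity model treats as reduced-birth days.

Date parsing is deliberately strict: the caller declares one of three date
dialects (ISO 8601 ``Y-M-D``, North American ``M/D/Y``, British/Australian
``D/M/Y``) and every record either parses under that dialect or is returned
as an explicit rejection.  No format guessing is performed — silent dialect
inference is itself a well-known source of birthdate contamination.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PersonRecord",
    "Rejection",
    "CalendarConfig",
    "DailyCountSeries",
    "parse_birthdates",
    "format_date",
    "aggregate_counts",
    "mark_special_days",
    "read_records",
    "read_counts",
    "read_holidays",
]

DIALECTS = ("iso", "us", "uk")

_DIALECT_PATTERNS = {
    "iso": re.compile(r"^\s*(\d{4})-(\d{1,2})-(\d{1,2})\s*$"),
    "us": re.compile(r"^\s*(\d{1,2})/(\d{1,2})/(\d{4})\s*$"),
    "uk": re.compile(r"^\s*(\d{1,2})/(\d{1,2})/(\d{4})\s*$"),
}


class EmptyDataError(ValueError):
    """Raised when an operation receives no usable records or dates."""


@dataclass(frozen=True)
class PersonRecord:
    """One person-level row: an opaque identifier and a raw birthdate string."""

    record_id: str
    birthdate_raw: str | None

    def __post_init__(self) -> None:
        if not str(self.record_id):
            raise ValueError("record_id must be non-empty")


@dataclass(frozen=True)
class Rejection:
    """A record that could not be mapped to a calendar date."""

    record_id: str
    birthdate_raw: str | None
    reason: str  # 'missing' | 'unparseable' | 'impossible_date' | 'out_of_bounds'


@dataclass(frozen=True)
class CalendarConfig:
    """Bookkeeping for the special-day indicator and date parsing.

    Parameters
    ----------
    weekend_days
        ISO weekday numbers (1=Monday .. 7=Sunday) treated as weekend.
    holidays
        Calendar dates treated like weekends when
        ``treat_holidays_as_weekend`` is true.
    date_dialect
        One of ``iso``, ``us``, ``uk``.
    """

    weekend_days: frozenset[int] = frozenset({6, 7})
    holidays: frozenset[_dt.date] = frozenset()
    date_dialect: str = "iso"
    treat_holidays_as_weekend: bool = True

    def __post_init__(self) -> None:
        if not set(self.weekend_days) <= set(range(1, 8)):
            raise ValueError("weekend_days must be ISO weekday numbers in 1..7")
        if self.date_dialect not in DIALECTS:
            raise ValueError(
                f"unknown date dialect {self.date_dialect!r}; expected one of {DIALECTS}"
            )


@dataclass
class DailyCountSeries:
    """Dense daily birthdate counts with a special-day indicator.

    Invariants (checked on construction): dates strictly increasing with no
    gaps, counts non-negative, all arrays of equal length.
    """

    dates: pd.DatetimeIndex
    counts: np.ndarray
    special: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.special is None:
            self.special = np.zeros(len(self.dates), dtype=np.int8)
        self.special = np.asarray(self.special, dtype=np.int8)
        if len(self.dates) == 0:
            raise EmptyDataError("series must contain at least one day")
        if len(self.counts) != len(self.dates) or len(self.special) != len(self.dates):
            raise ValueError("dates, counts and special must have equal length")
        diffs = np.diff(self.dates.asi8)
        if len(diffs) and not np.all(diffs == 86_400_000_000_000):
            raise ValueError("dates must be consecutive calendar days with no gaps")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(np.isin(self.special, [0, 1])):
            raise ValueError("special indicator must be 0/1")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def day_index(self) -> np.ndarray:
        """Integer day offsets from the first date (0, 1, 2, ...)."""
        return ((self.dates.asi8 - self.dates.asi8[0]) // 86_400_000_000_000).astype(
            np.int64
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates.strftime("%Y-%m-%d"),
                "count": self.counts,
                "special": self.special.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, date_col: str = "date", count_col: str = "count") -> "DailyCountSeries":
        dates = pd.DatetimeIndex(pd.to_datetime(df[date_col], format="%Y-%m-%d"))
        order = np.argsort(dates.asi8)
        dates = dates[order]
        counts = np.asarray(df[count_col], dtype=np.int64)[order]
        full = pd.date_range(dates[0], dates[-1], freq="D")
        dense = np.zeros(len(full), dtype=np.int64)
        pos = ((dates.asi8 - full.asi8[0]) // 86_400_000_000_000).astype(np.int64)
        np.add.at(dense, pos, counts)
        return cls(dates=full, counts=dense)


def _parse_one(raw: str, dialect: str) -> _dt.date:
    """Parse a single date string; raises ValueError with a reason tag."""
    m = _DIALECT_PATTERNS[dialect].match(raw)
    if m is None:
        raise ValueError("unparseable")
    a, b, c = (int(g) for g in m.groups())
    if dialect == "iso":
        y, mo, d = a, b, c
    elif dialect == "us":
        mo, d, y = a, b, c
    else:  # uk
        d, mo, y = a, b, c
    try:
        return _dt.date(y, mo, d)
    except ValueError as exc:
        raise ValueError("impossible_date") from exc


def format_date(date: _dt.date, dialect: str) -> str:
    """Render a date in the given dialect (zero-padded, the normalized form)."""
    if dialect == "iso":
        return f"{date.year:04d}-{date.month:02d}-{date.day:02d}"
    if dialect == "us":
        return f"{date.month:02d}/{date.day:02d}/{date.year:04d}"
    if dialect == "uk":
        return f"{date.day:02d}/{date.month:02d}/{date.year:04d}"
    raise ValueError(f"unknown date dialect {dialect!r}")


def parse_birthdates(
    records: Iterable[PersonRecord],
    dialect: str,
    min_date: _dt.date | None = None,
    max_date: _dt.date | None = None,
) -> tuple[list[_dt.date], list[Rejection]]:
    """Map each record to exactly one calendar date or one rejection.

    The two output lists partition the input: ``len(dates) + len(rejections)``
    equals the number of records.  Records outside ``[min_date, max_date]``
    (when given) are rejected with reason ``out_of_bounds``.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown date dialect {dialect!r}; expected one of {DIALECTS}")
    accepted: list[_dt.date] = []
    rejected: list[Rejection] = []
    for rec in records:
        raw = rec.birthdate_raw
        if raw is None or not str(raw).strip():
            rejected.append(Rejection(rec.record_id, raw, "missing"))
            continue
        try:
            date = _parse_one(str(raw), dialect)
        except ValueError as exc:
            rejected.append(Rejection(rec.record_id, raw, str(exc)))
            continue
        if (min_date is not None and date < min_date) or (
            max_date is not None and date > max_date
        ):
            rejected.append(Rejection(rec.record_id, raw, "out_of_bounds"))
            continue
        accepted.append(date)
    return accepted, rejected


def aggregate_counts(
    dates: Sequence[_dt.date],
    date_range: tuple[_dt.date, _dt.date] | None = None,
) -> DailyCountSeries:
    """Aggregate calendar dates to a dense daily count series.

    The series covers ``[min(dates), max(dates)]`` (or the explicit
    ``date_range``); days with no births appear with count zero, so the total
    count always equals the number of input dates that fall in range.
    """
    dates = list(dates)
    if not dates:
        raise EmptyDataError("no valid dates to aggregate")
    lo = min(dates) if date_range is None else date_range[0]
    hi = max(dates) if date_range is None else date_range[1]
    if lo > hi:
        raise ValueError("date range start after end")
    full = pd.date_range(lo, hi, freq="D")
    counts = np.zeros(len(full), dtype=np.int64)
    origin = full[0].date().toordinal()
    for d in dates:
        pos = d.toordinal() - origin
        if 0 <= pos < len(full):
            counts[pos] += 1
    return DailyCountSeries(dates=full, counts=counts)


def mark_special_days(series: DailyCountSeries, cfg: CalendarConfig) -> DailyCountSeries:
    """Set the special-day indicator from weekend weekdays and listed holidays.

    Idempotent: the indicator is fully recomputed from the configuration.
    """
    iso_weekday = series.dates.dayofweek.to_numpy() + 1  # pandas: Monday=0
    special = np.isin(iso_weekday, list(cfg.weekend_days))
    if cfg.treat_holidays_as_weekend and cfg.holidays:
        hol = np.array(
            [d.date() in cfg.holidays for d in series.dates], dtype=bool
        )
        special = special | hol
    return DailyCountSeries(
        dates=series.dates,
        counts=series.counts.copy(),
        special=special.astype(np.int8),
    )


def read_records(
    path: str,
    id_column: str = "id",
    date_column: str = "birthdate",
    delimiter: str = ",",
) -> list[PersonRecord]:
    """Read person records from a delimited text file with a header row."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in (id_column, date_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    return [
        PersonRecord(record_id=str(r), birthdate_raw=(b if b != "" else None))
        for r, b in zip(df[id_column], df[date_column])
    ]


def read_counts(path: str, delimiter: str = ",") -> DailyCountSeries:
    """Read a pre-aggregated two-column (date, count) file, dates in ISO 8601."""
    df = pd.read_csv(path, sep=delimiter)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("counts file must have at least two columns: date, count")
    return DailyCountSeries.from_frame(df, date_col=cols[0], count_col=cols[1])


def read_holidays(path: str) -> frozenset[_dt.date]:
    """Read a holiday file: one ISO 8601 date per line, '#' comments allowed."""
    out: set[_dt.date] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            out.add(_dt.date.fromisoformat(line))
    return frozenset(out)
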