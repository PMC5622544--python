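"""Calendar-month arithmetic.

The registry's time unit is the calendar month: timelines index events by
(year*12 + month) differences from the diagnosis date, and therapy spans
count every month they overlap, partial months included.
"""

from __future__ import annotations

import datetime as dt


def parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def add_months(day: dt.date, months: int) -> dt.date:
    """Shift by whole months, clamping the day-of-month (31 Jan + 1m = 28 Feb)."""
    total = day.year * 12 + (day.month - 1) + months
    year, month = divmod(total, 12)
    month += 1
    last = _days_in_month(year, month)
    return dt.date(year, month, min(day.day, last))


def month_index(day: dt.date, origin: dt.date) -> int:
    """Calendar-month difference between *day* and *origin* (0-based)."""
    return (day.year - origin.year) * 12 + (day.month - origin.month)


def _days_in_month(year: int, month: int) -> int:
    if month == 12:
        return 31
    return (dt.date(year, month + 1, 1) - dt.timedelta(days=1)).day
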