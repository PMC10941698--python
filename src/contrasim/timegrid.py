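"""Calendar-month arithmetic.

The simulation runs on a whole-calendar-month grid.  A month is an integer
index ``year * 12 + (month - 1)`` so that differences are months elapsed;
helpers convert to/from (year, month) and to first-of-month dates for the
day-resolution appointment logic.
"""

from __future__ import annotations

import datetime


def month_index(year: int, month: int = 1) -> int:
    """Absolute month index of a calendar (year, month)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month {month} not in 1..12")
    return year * 12 + (month - 1)


def year_of(m: int) -> int:
    return m // 12


def month_of(m: int) -> int:
    return m % 12 + 1


def date_of(m: int) -> datetime.date:
    """First day of the month with index ``m``."""
    return datetime.date(year_of(m), month_of(m), 1)


def ordinal_of(m: int) -> int:
    """Proleptic-Gregorian ordinal of the first day of month ``m``."""
    return date_of(m).toordinal()
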