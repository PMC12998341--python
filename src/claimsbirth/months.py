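"""Month-granular time arithmetic.

All event timing in administrative claims extracts considered here is
month-granular: a claim line carries a billing year and month, and the
mother-child linkage gives the child's birth year and month. Times are
therefore encoded as a single integer month index,

    index = year * 12 + (month - 1),

which is bijective with (year, month) and makes whole-month differences,
age-in-completed-years and window comparisons plain integer arithmetic.
Observation windows are half-open ``[start, end)`` at month granularity.
"""

from __future__ import annotations

import re

__all__ = [
    "month_index",
    "year_month",
    "parse_ym",
    "format_ym",
    "age_completed_years",
]

_YM_RE = re.compile(r"^(\d{4})-(\d{1,2})$")


def month_index(year: int, month: int) -> int:
    """Encode (year, month) as an integer month count.

    ``month`` is 1-based (January = 1).
    """
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month!r}")
    return int(year) * 12 + (int(month) - 1)


def year_month(index: int) -> tuple[int, int]:
    """Decode a month index back to (year, month)."""
    index = int(index)
    return index // 12, index % 12 + 1


def parse_ym(text: str) -> int:
    """Parse ``'YYYY-MM'`` into a month index."""
    m = _YM_RE.match(text.strip())
    if m is None:
        raise ValueError(f"expected 'YYYY-MM', got {text!r}")
    return month_index(int(m.group(1)), int(m.group(2)))


def format_ym(index: int) -> str:
    """Format a month index as ``'YYYY-MM'``."""
    y, m = year_month(index)
    return f"{y:04d}-{m:02d}"


def age_completed_years(birth: int, event: int) -> int:
    """Age in completed years at ``event`` for someone born in month ``birth``.

    Month-granular floor: a woman born 1990-04 is 29 in 2020-03 and 30 in
    2020-04. Raises ``ValueError`` if the event precedes the birth month.
    """
    if event < birth:
        raise ValueError(
            f"event month {format_ym(event)} precedes birth month {format_ym(birth)}"
        )
    return (int(event) - int(birth)) // 12
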