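"""ISO-week calendar helpers: one time axis (decimal years) for all modules."""

from __future__ import annotations

import datetime as _dt


def iso_weeks(year_start: int, year_end: int) -> list[tuple[int, int]]:
    """All (iso_year, iso_week) pairs from year_start-W01 through year_end's last week."""
    out = []
    for year in range(year_start, year_end + 1):
        n_weeks = _dt.date(year, 12, 28).isocalendar()[1]  # 52 or 53
        out.extend((year, w) for w in range(1, n_weeks + 1))
    return out


def iso_week_midpoint(iso_year: int, iso_week: int) -> float:
    """Decimal-year midpoint of an ISO week (its Thursday, mid-day)."""
    thursday = _dt.date.fromisocalendar(iso_year, iso_week, 4)
    year_start = _dt.date(thursday.year, 1, 1)
    n_days = (_dt.date(thursday.year + 1, 1, 1) - year_start).days
    doy = (thursday - year_start).days + 1
    return thursday.year + (doy - 0.5) / n_days
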