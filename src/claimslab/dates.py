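"""Calendar arithmetic: inclusive day counts, Japanese fiscal years, month keys."""

from __future__ import annotations

from datetime import date

MonthKey = tuple[int, int]


def window_length_days(start: date, end: date) -> int:
    """Inclusive number of days from ``start`` to ``end``.

    Both endpoints count, so ``window_length_days(d, d) == 1``.
    """
    if start > end:
        raise ValueError(f"start {start} is after end {end}")
    return (end - start).days + 1


def fiscal_year(d: date) -> int:
    """Japanese fiscal year containing ``d``.

    Fiscal year ``y`` runs April 1 of calendar year ``y`` through March 31
    of ``y + 1`` and is labeled by the starting calendar year.
    """
    return d.year if d.month >= 4 else d.year - 1


def month_key(d: date) -> MonthKey:
    """Calendar ``(year, month)`` of ``d``."""
    return (d.year, d.month)


def month_index(key: MonthKey) -> int:
    """Serial month number; consecutive calendar months differ by exactly 1."""
    y, m = key
    return y * 12 + (m - 1)


def month_from_index(i: int) -> MonthKey:
    return (i // 12, i % 12 + 1)
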