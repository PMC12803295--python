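"""Named synthetic flag fixtures for deterministic replay.

The ``table2`` fixture is a synthetic error-flag table whose per-domain
monthly counts start and end on fixed dates and counts (Imaging 2024-03-13
with 16 errors down to 2025-08-13 with 1, and so on), with deterministically
interpolated months in between.  Replaying it through the monthly-count and
percent-change operations reproduces a known observed-change column and the
study-wide drop from 40 errors in the domains' first months to 6 in their
last.  All identifiers in it are synthetic.
"""

from __future__ import annotations

import calendar
import datetime as dt

import pandas as pd

from .checks import FLAG_COLUMNS
from .simulate import months_between

__all__ = ["replay_fixture", "available_fixtures"]

# domain, form, site, first date, first count, last date, last count
_TABLE2_ROWS = (
    ("BloodCollection", "blood_collection", "MCC1-A", dt.date(2024, 8, 27), 6, dt.date(2025, 7, 16), 2),
    ("FunctionalTesting", "functional_testing", "MCC1-B", dt.date(2024, 11, 6), 1, dt.date(2025, 7, 16), 2),
    ("Imaging", "imaging", "MCC2-A", dt.date(2024, 3, 13), 16, dt.date(2025, 8, 13), 1),
    ("QST", "qst", "MCC2-B", dt.date(2024, 8, 27), 17, dt.date(2025, 8, 13), 1),
)

_CENTER = {"MCC1-A": "MCC1", "MCC1-B": "MCC1", "MCC2-A": "MCC2", "MCC2-B": "MCC2"}


def _interpolated_count(first: int, last: int, k: int, span: int) -> int:
    """Geometric interpolation between the endpoint counts, rounded."""
    ratio = (max(last, 1) / max(first, 1)) ** (k / span)
    return max(int(round(first * ratio)), 0)


def _table2_flags() -> pd.DataFrame:
    rows = []
    for domain, form, site, first_date, first_count, last_date, last_count in _TABLE2_ROWS:
        span = months_between(first_date, last_date)
        serial = 0

        def flag(date: dt.date, domain=domain, form=form, site=site):
            nonlocal serial
            serial += 1
            return {
                "subject_id": f"SYN-{form}-{serial:03d}",
                "site_id": site,
                "domain": domain,
                "form_id": form,
                "visit": "baseline",
                "check_id": f"{form}_fixture",
                "fields": "",
                "values": "",
                "flag_date": date,
                "message": "synthetic fixture flag",
                "center": _CENTER[site],
                "cohort": "TKA",
                "delivery_instrument": "in-person",
            }

        # first month: earliest flag on the anchor date, the rest after it
        month_end = calendar.monthrange(first_date.year, first_date.month)[1]
        rows.append(flag(first_date))
        for j in range(1, first_count):
            rows.append(flag(first_date.replace(day=min(first_date.day + j, month_end))))
        # interior months on the 15th
        for k in range(1, span):
            month = first_date.month - 1 + k
            date = dt.date(first_date.year + month // 12, month % 12 + 1, 15)
            for _ in range(_interpolated_count(first_count, last_count, k, span)):
                rows.append(flag(date))
        # last month: latest flag on the anchor date, the rest before it
        for j in range(last_count - 1, 0, -1):
            rows.append(flag(last_date.replace(day=max(last_date.day - j, 1))))
        rows.append(flag(last_date))
    return pd.DataFrame(rows, columns=list(FLAG_COLUMNS))


_FIXTURES = {"table2": _table2_flags}


def available_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def replay_fixture(name: str) -> pd.DataFrame:
    """Return the named synthetic flag table.

    Raises ValueError listing the available fixtures for unknown names.
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; available: {available_fixtures()}") from None
    return builder()
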