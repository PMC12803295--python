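"""Time-windowed site-level error reports and instrument breakdowns.

Error flags are binned by age relative to an as-of date into three windows —
recent (< 90 days), mid (90-180 days, both endpoints included) and archive
(> 180 days) — and reported per center x surgical-cohort stratum and CRF
domain.  Reports export to CSV, Excel, or a standalone printable HTML page
with identical content; CSV bytes are stable across runs.  A separate
tabulation breaks patient-reported-outcome errors down by survey delivery
instrument so missingness can be compared between REDCap and MyDataHelps
sites.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from .schema import StudySchema
from .util import round_half_away

__all__ = [
    "WINDOWS",
    "window_assign",
    "build_report",
    "export_report",
    "export_workbook",
    "instrument_breakdown",
    "ErrorReport",
]

WINDOWS = ("recent", "mid", "archive")
EXPORT_FORMATS = ("csv", "xlsx", "html")

#: fixed report column order
REPORT_COLUMNS = ("subject_id", "site_id", "visit", "form_id", "check_id", "fields", "values", "flag_date", "message")


def window_assign(flag_date: dt.date, as_of: dt.date) -> str:
    """Window for one flag: age in whole days; recent [0, 90), mid [90, 180],
    archive (180, inf).  A future flag date is an error."""
    age = (as_of - flag_date).days
    if age < 0:
        raise ValueError(f"flag_date {flag_date} is after as_of {as_of}")
    if age < 90:
        return "recent"
    if age <= 180:
        return "mid"
    return "archive"


@dataclass
class ErrorReport:
    """Rows for one center x cohort x domain x window, plus metadata."""

    center: str
    cohort: str
    domain: str
    window: str
    as_of: dt.date
    rows: pd.DataFrame

    @property
    def title(self) -> str:
        return f"{self.center} {self.cohort} — {self.domain} — {self.window} (as of {self.as_of})"


def build_report(
    flags: pd.DataFrame, center: str, cohort: str, domain: str, window: str, as_of: dt.date
) -> ErrorReport:
    """Filter flags to one stratum/domain/window; rows sorted stably so the
    same inputs regenerate a bit-identical report."""
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}, got {window!r}")
    sel = flags[(flags["center"] == center) & (flags["cohort"] == cohort) & (flags["domain"] == domain)]
    if not sel.empty:
        in_window = sel["flag_date"].map(lambda d: window_assign(d, as_of) == window)
        sel = sel[in_window]
    rows = (
        sel.reindex(columns=list(REPORT_COLUMNS))
        .sort_values(["subject_id", "visit", "check_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return ErrorReport(center=center, cohort=cohort, domain=domain, window=window, as_of=as_of, rows=rows)


def _as_csv_frame(report: ErrorReport) -> pd.DataFrame:
    frame = report.rows.copy()
    frame["flag_date"] = frame["flag_date"].map(lambda d: d.isoformat() if isinstance(d, dt.date) else "")
    return frame


def export_report(report: ErrorReport, path, fmt: str = "csv") -> None:
    """Write one report as csv, xlsx, or standalone html (content-equal)."""
    frame = _as_csv_frame(report)
    if fmt == "csv":
        frame.to_csv(path, index=False, lineterminator="\n")
    elif fmt == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            frame.to_excel(writer, sheet_name=report.domain[:31], index=False)
    elif fmt == "html":
        table = frame.to_html(index=False, border=0)
        page = (
            "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>{report.title}</title></head>"
            f"<body><h2>{report.title}</h2>{table}</body></html>"
        )
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(page)
    else:
        raise ValueError(f"unknown format {fmt!r}; supported: {EXPORT_FORMATS}")


def export_workbook(reports: list[ErrorReport], path) -> None:
    """Spreadsheet export with one sheet per domain."""
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for report in reports:
            _as_csv_frame(report).to_excel(writer, sheet_name=report.domain[:31], index=False)


def instrument_breakdown(flags: pd.DataFrame, schema: StudySchema) -> pd.DataFrame:
    """Percentage of each PRO error type per form x site.

    Each row carries the site's delivery instrument; whether missingness
    differs by instrument is the reader's comparison — this only tabulates.
    Percentages sum to 100 over error types within each (form, site).
    """
    pro_forms = {f.form_id for f in schema.forms if f.kind == "PRO"}
    sel = flags[flags["form_id"].isin(pro_forms)]
    columns = ["form_id", "site_id", "delivery_instrument", "error_type", "n", "percentage"]
    if sel.empty:
        return pd.DataFrame(columns=columns)
    rows = []
    for (form_id, site_id), group in sel.groupby(["form_id", "site_id"], sort=True):
        total = len(group)
        for check_id, n in group["check_id"].value_counts().sort_index().items():
            rows.append(
                {
                    "form_id": form_id,
                    "site_id": site_id,
                    "delivery_instrument": group["delivery_instrument"].iloc[0],
                    "error_type": check_id,
                    "n": int(n),
                    "percentage": round_half_away(100.0 * int(n) / total, 1),
                }
            )
    return pd.DataFrame(rows, columns=columns)
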