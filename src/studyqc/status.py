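"""Completion/error status classification, subject streaks and UpSet counts.

Every (subject, visit, form) cell gets exactly one of five statuses:

* ``complete_no_error``      — status field says complete, no flags
* ``complete_with_error``    — complete but at least one edit-check flag
* ``incomplete``             — status field says incomplete or unverified
* ``unknown``                — status field blank
* ``not_collected_by_design``— the form's applicability excludes this cell

Subject-level streaks summarize whether all primary biomarker forms due so
far are in hand (with or without errors), and exclusive combination counts
("which exact subset of tracked forms is complete without errors") feed
UpSet-style completeness displays at two anchors: under 35 days after
baseline, and beyond seven calendar months.
"""

from __future__ import annotations

import datetime as dt
import warnings

import pandas as pd

from .schema import STATUS_COMPLETE, STATUS_INCOMPLETE, STATUS_UNVERIFIED, StudySchema, is_missing
from .simulate import add_months
from .util import round_half_away

__all__ = [
    "STATUSES",
    "classify_form",
    "form_status_table",
    "quadrant_percentages",
    "classify_streak",
    "streak_table",
    "baseline_dates",
    "combination_counts",
    "marginal_counts",
    "upset_membership_matrix",
    "cell_codes",
]

COMPLETE_NO_ERROR = "complete_no_error"
COMPLETE_WITH_ERROR = "complete_with_error"
INCOMPLETE = "incomplete"
UNKNOWN = "unknown"
NOT_COLLECTED = "not_collected_by_design"

STATUSES = (COMPLETE_NO_ERROR, COMPLETE_WITH_ERROR, INCOMPLETE, UNKNOWN, NOT_COLLECTED)
QUADRANTS = STATUSES[:4]

STREAK_NO_ERRORS = "complete_streak_no_errors"
STREAK_WITH_ERRORS = "streak_with_errors"
STREAK_INCOMPLETE = "incomplete_streak"

#: primary biomarker forms used for streaks unless configured otherwise
DEFAULT_PRIMARY_FORMS = ("imaging", "qst", "functional_testing", "blood_collection")

_COLOR = {COMPLETE_NO_ERROR: "blue", COMPLETE_WITH_ERROR: "green", NOT_COLLECTED: "yellow"}


def classify_form(status_value, n_flags: int, applicable: bool) -> str:
    """Classify one form instance from its completion status and flag count."""
    if not applicable:
        return NOT_COLLECTED
    if is_missing(status_value):
        return UNKNOWN
    try:
        code = int(float(status_value))
    except (TypeError, ValueError):
        code = -1
    if code in (STATUS_INCOMPLETE, STATUS_UNVERIFIED):
        return INCOMPLETE
    if code == STATUS_COMPLETE:
        return COMPLETE_WITH_ERROR if n_flags > 0 else COMPLETE_NO_ERROR
    warnings.warn(f"completion status {status_value!r} outside {{0,1,2,missing}}; treated as unknown")
    return UNKNOWN


def form_status_table(records: pd.DataFrame, flags: pd.DataFrame, schema: StudySchema) -> pd.DataFrame:
    """One status row per (subject, visit) present in the records x every form."""
    events = records[["subject_id", "site_id", "cohort", "visit"]].drop_duplicates()
    status_values = {
        (r.subject_id, r.visit, r.form_id): r.value
        for r in records[records["field_name"].isin([f.status_field for f in schema.forms])].itertuples()
    }
    flagged = set(zip(flags["subject_id"], flags["visit"], flags["form_id"])) if len(flags) else set()

    rows = []
    for event in events.itertuples():
        for form in schema.forms:
            applicable = form.applicability.applies(event.cohort, event.visit)
            key = (event.subject_id, event.visit, form.form_id)
            status = classify_form(status_values.get(key), int(key in flagged), applicable)
            rows.append(
                {
                    "subject_id": event.subject_id,
                    "site_id": event.site_id,
                    "cohort": event.cohort,
                    "visit": event.visit,
                    "form_id": form.form_id,
                    "status": status,
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "site_id", "cohort", "visit", "form_id", "status"])


def quadrant_percentages(
    statuses: pd.DataFrame,
    sites: list[str] | None = None,
    visits: list[str] | None = None,
    forms: list[str] | None = None,
) -> dict[str, float]:
    """Four-quadrant percentages over applicable instances in the selection.

    Design-excluded cells leave the denominator; the four percentages sum to
    100 before rounding (one decimal, half away from zero).  An empty
    selection yields an empty dict rather than a division error.
    """
    sel = statuses
    if sites is not None:
        sel = sel[sel["site_id"].isin(sites)]
    if visits is not None:
        sel = sel[sel["visit"].isin(visits)]
    if forms is not None:
        sel = sel[sel["form_id"].isin(forms)]
    sel = sel[sel["status"] != NOT_COLLECTED]
    if sel.empty:
        return {}
    counts = sel["status"].value_counts()
    total = int(counts.sum())
    return {q: round_half_away(100.0 * int(counts.get(q, 0)) / total, 1) for q in QUADRANTS}


# ---------------------------------------------------------------------------
# streaks
# ---------------------------------------------------------------------------


def baseline_dates(records: pd.DataFrame, schema: StudySchema) -> pd.Series:
    """Per-subject baseline visit date (entry timestamp of the first visit)."""
    base_visit = schema.visits[0].name
    sub = records[(records["visit"] == base_visit) & records["entry_timestamp"].notna()]
    return sub.groupby("subject_id")["entry_timestamp"].min()


def _due_visits(schema: StudySchema, baseline: dt.date, as_of: dt.date) -> list[str]:
    elapsed = (as_of - baseline).days
    return [v.name for v in schema.visits if v.offset_days <= elapsed]


def classify_streak(
    subject_statuses: pd.DataFrame,
    cohort: str,
    schema: StudySchema,
    baseline: dt.date,
    as_of: dt.date,
    primary_forms: tuple[str, ...] = DEFAULT_PRIMARY_FORMS,
) -> str:
    """Streak status of one subject over due visits of the primary forms.

    A visit is due once its nominal offset has elapsed; an applicable primary
    form with no status row at a due visit counts as incomplete.
    """
    lookup = {
        (r.visit, r.form_id): r.status for r in subject_statuses.itertuples()
    }
    any_error = False
    for visit in _due_visits(schema, baseline, as_of):
        for form_id in primary_forms:
            form = schema.form(form_id)
            if not form.applicability.applies(cohort, visit):
                continue
            status = lookup.get((visit, form_id), INCOMPLETE)
            if status in (INCOMPLETE, UNKNOWN):
                return STREAK_INCOMPLETE
            if status == COMPLETE_WITH_ERROR:
                any_error = True
    return STREAK_WITH_ERRORS if any_error else STREAK_NO_ERRORS


def streak_table(
    statuses: pd.DataFrame,
    records: pd.DataFrame,
    schema: StudySchema,
    as_of: dt.date,
    primary_forms: tuple[str, ...] = DEFAULT_PRIMARY_FORMS,
) -> pd.DataFrame:
    """Streak status per subject with a baseline date; others are excluded."""
    baselines = baseline_dates(records, schema)
    cohorts = records.drop_duplicates("subject_id").set_index("subject_id")["cohort"]
    rows = []
    for subject, baseline in baselines.items():
        sub = statuses[statuses["subject_id"] == subject]
        rows.append(
            {
                "subject_id": subject,
                "streak": classify_streak(sub, cohorts[subject], schema, baseline, as_of, primary_forms),
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "streak"])


# ---------------------------------------------------------------------------
# UpSet combination counts
# ---------------------------------------------------------------------------


def _stratum_subjects(baselines: pd.Series, as_of: dt.date, anchor: str) -> list[str]:
    if anchor == "early":
        return [s for s, b in baselines.items() if (as_of - b).days < 35]
    if anchor == "late":
        return [s for s, b in baselines.items() if as_of > add_months(b, 7)]
    raise ValueError(f"anchor must be 'early' or 'late', got {anchor!r}")


def upset_membership_matrix(
    statuses: pd.DataFrame,
    records: pd.DataFrame,
    schema: StudySchema,
    as_of: dt.date,
    anchor: str,
    tracked_forms: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Boolean membership per subject in the anchor stratum.

    A subject is a member of form F when at least one applicable instance of
    F was due and every due applicable instance is complete without errors.
    The matrix (subject x form booleans plus site_id) is the export format
    standard UpSet plotting tools consume.
    """
    tracked = tuple(tracked_forms) if tracked_forms else tuple(f.form_id for f in schema.forms)
    baselines = baseline_dates(records, schema)
    cohorts = records.drop_duplicates("subject_id").set_index("subject_id")["cohort"]
    sites = records.drop_duplicates("subject_id").set_index("subject_id")["site_id"]
    subjects = _stratum_subjects(baselines, as_of, anchor)

    rows = []
    for subject in subjects:
        sub = statuses[statuses["subject_id"] == subject]
        lookup = {(r.visit, r.form_id): r.status for r in sub.itertuples()}
        row = {"subject_id": subject, "site_id": sites[subject]}
        for form_id in tracked:
            form = schema.form(form_id)
            due = [
                v
                for v in _due_visits(schema, baselines[subject], as_of)
                if form.applicability.applies(cohorts[subject], v)
            ]
            row[form_id] = bool(due) and all(lookup.get((v, form_id)) == COMPLETE_NO_ERROR for v in due)
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "site_id", *tracked])


def combination_counts(
    statuses: pd.DataFrame,
    records: pd.DataFrame,
    schema: StudySchema,
    as_of: dt.date,
    anchor: str,
    tracked_forms: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Exclusive combination counts per site: one row per observed exact
    subset of tracked forms complete without errors, with its subject count."""
    membership = upset_membership_matrix(statuses, records, schema, as_of, anchor, tracked_forms)
    tracked = [c for c in membership.columns if c not in ("subject_id", "site_id")]
    if membership.empty:
        return pd.DataFrame(columns=["site_id", *tracked, "count"])
    out = (
        membership.groupby(["site_id", *tracked], as_index=False, observed=True)
        .agg(count=("subject_id", "size"))
        .sort_values(["site_id", *tracked], kind="mergesort")
        .reset_index(drop=True)
    )
    return out[["site_id", *tracked, "count"]]


def marginal_counts(combos: pd.DataFrame) -> pd.DataFrame:
    """Per-form totals (UpSet horizontal bars): subjects completing each form,
    i.e. the sum of exclusive counts over subsets containing the form."""
    tracked = [c for c in combos.columns if c not in ("site_id", "count")]
    rows = []
    for site, group in combos.groupby("site_id"):
        for form in tracked:
            rows.append({"site_id": site, "form_id": form, "count": int(group.loc[group[form], "count"].sum())})
    return pd.DataFrame(rows, columns=["site_id", "form_id", "count"])


# ---------------------------------------------------------------------------
# cell color coding
# ---------------------------------------------------------------------------


def cell_codes(statuses: pd.DataFrame, flags: pd.DataFrame) -> pd.DataFrame:
    """Color per (subject, form, visit) cell: blue = error-free, green = has
    errors (tooltip carries the messages), yellow = not collected by design;
    incomplete/unknown cells stay white."""
    messages: dict[tuple, str] = {}
    for r in flags.itertuples():
        key = (r.subject_id, r.visit, r.form_id)
        messages[key] = (messages[key] + "; " if key in messages else "") + r.message
    out = statuses.copy()
    out["color"] = out["status"].map(_COLOR).fillna("white")
    out["tooltip"] = [
        messages.get((r.subject_id, r.visit, r.form_id), "") if r.status == COMPLETE_WITH_ERROR else ""
        for r in out.itertuples()
    ]
    return out[["subject_id", "site_id", "visit", "form_id", "status", "color", "tooltip"]]
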